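"""Autonomic psychophysiology pipeline: RSA from ECG, heartbeat-counting
interoceptive accuracy, and the inferential battery used alongside them.

The package is organised around the processing chain of a typical
interoception/proxemics study:

``ingest``
    ECG reading, R-peak detection, R-R interval construction, and
    artifact flagging/editing on the beat series.
``rsa``
    Respiratory sinus arrhythmia as the natural log of band-passed
    (0.12-0.40 Hz) heart-period variance, with 30-s epoching, condition
    averaging and baseline-referenced reactivity.
``interoception``
    Heartbeat-counting (mental tracking) accuracy scores.
``stats``
    Group t-tests, ANCOVA with adjusted marginal means, mixed
    within-between ANOVA with Tukey post hocs, correlation battery with
    Fisher r-to-z comparison, simple regression, outlier screening.
``synth``
    Seeded generators with known ground truth for every stage.
``cli``
    Command-line entry points over the library.
"""

from importlib import resources

import pandas as pd

__version__ = "0.1.0"


def load_table2() -> pd.DataFrame:
    """Load the bundled cohort table of the 24 anorexia patients.

    Columns: ``id, age, age_of_onset, illness_duration_years, ia,
    resting_rsa_ln_ms2``.  ``ia`` is the heartbeat-counting accuracy in
    [0, 1]; ``resting_rsa_ln_ms2`` is resting RSA in ln(ms^2).
    """
    with resources.files("interorsa.data").joinpath(
        "table2_an_patients.csv"
    ).open() as fh:
        return pd.read_csv(fh)
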