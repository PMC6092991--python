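"""Bundled reference tables: published per-subject results on the BCI
Competition IV dataset 2a (9 subjects, 4 motor-imagery classes) for the
source-space ROI-CSP ensemble decoder and the conventional sensor-space
CSP baseline.

These tables are *inputs* for the comparison utilities — accuracy (%),
Cohen's kappa, and one-vs-rest sensitivity/specificity (%) per class —
each with the subject rows A01T..A09T plus the published ``Mean`` row.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_published_results"]

_FILES = {
    "accuracy": "bciciv2a_accuracy.csv",
    "kappa": "bciciv2a_kappa.csv",
    "sensitivity_sensor": "bciciv2a_sensitivity_sensor.csv",
    "sensitivity_source": "bciciv2a_sensitivity_source.csv",
    "specificity_sensor": "bciciv2a_specificity_sensor.csv",
    "specificity_source": "bciciv2a_specificity_source.csv",
}


def load_published_results() -> dict[str, pd.DataFrame]:
    """Return the bundled benchmark tables keyed by name.

    Keys: ``accuracy`` (columns sensor/source, %), ``kappa`` (columns
    sensor/source/winner_fbcsp), and per-class ``sensitivity_*`` /
    ``specificity_*`` for both arms (%); all indexed by subject with a
    trailing ``Mean`` row.
    """
    out = {}
    for key, fname in _FILES.items():
        with resources.files("roicsp.data").joinpath(fname).open() as fh:
            out[key] = pd.read_csv(fh, index_col="subject")
    return out
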