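"""Packaged reference tables for the published imidazol-5-one QSAR study.

The files here are one-time transcriptions of the published tables this
package can re-derive numbers from:

* ``validation_set.csv`` — the 12 validation compounds with their observed
  pIC50, the four model-1 descriptors (MATS4e, GATS5e, SpMax4_Bhs, RDF150u)
  and the printed model-1 predictions.
* ``model1_predictions.csv`` — observed pIC50, printed model-1 prediction
  and residual for all 39 compounds, with the calibration/validation set
  assignment.
* ``designed_properties.csv`` — physicochemical properties of the 18
  designed derivative compounds used for drug-likeness screening.
* ``published_models.json`` — the four published regression equations at
  full printed precision.

``manifest.json`` carries SHA-256 checksums of the data files so an
accidental edit is caught by the test suite.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from ..regression import LinearModel

__all__ = [
    "load_validation_set",
    "load_model1_predictions",
    "load_designed_properties",
    "load_published_models",
    "verify_checksums",
    "PRINTED",
]

#: Statistics exactly as printed in the study, for comparison reports.
PRINTED = {
    "r2_train": 0.6981,
    "r2_adj": 0.6433,
    "q2_loo": 0.5460,
    "r2_pred": 0.5357,
    "ss_res_test": 0.713008,
    "ss_tot_test": 1.535707,
    "train_mean_pic50": 4.5364,
    "warning_leverage": 0.56,
    "n_train": 27,
    "n_test": 12,
    "n_descriptors": 4,
}

_DATA_FILES = (
    "validation_set.csv",
    "model1_predictions.csv",
    "designed_properties.csv",
    "published_models.json",
)


def _path(name: str):
    return resources.files(__package__).joinpath(name)


def load_validation_set() -> pd.DataFrame:
    """Validation-set compounds: observed pIC50, model-1 descriptors and
    printed predictions, indexed by compound id."""
    with _path("validation_set.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"compound_id": str})
    return df.set_index("compound_id")


def load_model1_predictions() -> pd.DataFrame:
    """All 39 compounds: observed pIC50, printed model-1 prediction and
    residual, and calibration/validation assignment."""
    with _path("model1_predictions.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"compound_id": str})
    return df.set_index("compound_id")


def load_designed_properties() -> pd.DataFrame:
    """Physicochemical property table of the 18 designed compounds."""
    with _path("designed_properties.csv").open() as fh:
        return pd.read_csv(fh, dtype={"compound_id": str})


def load_published_models() -> dict[int, LinearModel]:
    """The four published equations keyed by model number."""
    with _path("published_models.json").open() as fh:
        entries = json.load(fh)
    return {i + 1: LinearModel.from_dict(e) for i, e in enumerate(entries)}


def verify_checksums() -> dict[str, bool]:
    """Compare each packaged data file against its recorded SHA-256."""
    with _path("manifest.json").open() as fh:
        manifest = json.load(fh)
    out = {}
    for name in _DATA_FILES:
        digest = hashlib.sha256(_path(name).read_bytes()).hexdigest()
        out[name] = digest == manifest[name]
    return out
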