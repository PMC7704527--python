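"""End-to-end study orchestration and the published-table reproduction report.

``run_full_study`` sequences the whole workflow — read, pretreat, split,
genetic descriptor search, internal/external validation, applicability
domain and (optionally) drug-likeness screening — and writes every stage
output under one directory.  ``reproduce_paper_tables`` recomputes the
statistics that are derivable from the packaged published tables and lists
printed-vs-recomputed pairs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .data import (
    activities_series,
    kennard_stone,
    pretreat,
    read_compound_table,
    read_descriptor_matrix,
)
from .gfa import GfaConfig, evolve
from .model import QsarModel
from .screening import published_model, read_property_table, screen_table
from .validation import adjusted_r2, external_r2pred, warning_leverage

logger = logging.getLogger("qsarlab")

__all__ = ["StudyConfig", "StudyReport", "run_full_study", "reproduce_paper_tables"]


@dataclass
class StudyConfig:
    """Inputs and knobs of a full study run."""

    descriptor_csv: str
    activity_csv: str
    output_dir: str
    property_csv: str | None = None
    n_train: int | None = None
    train_fraction: float | None = 0.7
    variance_tol: float = 1e-8
    corr_threshold: float = 0.99
    gfa: GfaConfig = field(default_factory=GfaConfig)
    top_k: int = 5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "gfa" in raw and isinstance(raw["gfa"], dict):
            raw["gfa"] = GfaConfig(**raw["gfa"])
        return cls(**raw)


@dataclass
class StudyReport:
    """Serializable record of everything a study run computed."""

    config: dict
    pretreatment: dict
    split: dict
    best_model: dict
    ranked_models: list
    internal: dict
    external: dict
    diagnostics: dict
    domain: dict
    criteria: dict
    screening: dict | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.ndarray, pd.Series)):
        return np.asarray(obj).tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    return str(obj)


def run_full_study(config: StudyConfig) -> StudyReport:
    """Run the complete workflow described by ``config``.

    Deterministic for a fixed ``config.gfa.seed``.  Writes ``split.csv``,
    ``best_model.json``, ``williams.csv``, ``report.json`` (and
    ``screening.csv`` when a property table is given) into
    ``config.output_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage=read descriptors=%s activities=%s",
                config.descriptor_csv, config.activity_csv)
    X = read_descriptor_matrix(config.descriptor_csv)
    y = activities_series(read_compound_table(config.activity_csv))
    shared = [i for i in X.index if i in set(y.index)]
    if not shared:
        raise ValueError("descriptor and activity tables share no compound ids")
    X, y = X.loc[shared], y.loc[shared]
    logger.info("stage=read n_compounds=%d n_descriptors=%d", *X.shape)

    X_clean, report = pretreat(X, config.variance_tol, config.corr_threshold)
    logger.info("stage=pretreat kept=%d removed_constant=%d removed_correlated=%d",
                report.n_kept, len(report.removed_constant),
                len(report.removed_correlated))

    split = kennard_stone(X_clean, n_train=config.n_train,
                          train_fraction=config.train_fraction
                          if config.n_train is None else None)
    split.to_frame().to_csv(out / "split.csv", index=False)
    X_train, y_train = X_clean.loc[split.train_ids], y.loc[split.train_ids]
    X_test, y_test = X_clean.loc[split.test_ids], y.loc[split.test_ids]
    logger.info("stage=split n_train=%d n_test=%d",
                len(split.train_ids), len(split.test_ids))

    gfa = evolve(X_train, y_train, config.gfa)
    best = gfa.best
    logger.info("stage=gfa evaluated=%d best_lof=%.5g support=%s",
                gfa.n_evaluated, best.lof, best.model.descriptor_names)
    best.model.to_json(out / "best_model.json")

    results = QsarModel(y_train, X_train,
                        support=best.model.descriptor_names).fit(name="gfa_best")
    internal = results.internal_validation()
    external = results.external_validation(X_test, y_test)
    diagnostics = results.diagnostics()
    domain = results.applicability_domain(X_query=X_test, y_query=y_test)
    domain.table.rename_axis("compound_id").to_csv(out / "williams.csv")
    criteria = results.criteria(external=external, internal=internal)
    logger.info("stage=validate r2=%.4f q2=%.4f r2_pred=%.4f pass=%s",
                internal.r2, internal.q2_loo, external.r2_pred,
                criteria.overall_pass)

    screening = None
    if config.property_csv:
        profiles = read_property_table(config.property_csv)
        summary = screen_table(profiles)
        summary.to_frame().to_csv(out / "screening.csv", index=False)
        screening = {
            "n_compounds": len(summary.ro5),
            "n_passing_ro5": summary.n_passing_ro5,
            "n_failing_ro5": summary.n_failing_ro5,
        }
        logger.info("stage=screen n=%d pass_ro5=%d",
                    screening["n_compounds"], screening["n_passing_ro5"])

    report_obj = StudyReport(
        config={**asdict(config), "gfa": asdict(config.gfa)},
        pretreatment={
            "removed_constant": report.removed_constant,
            "removed_correlated": [list(p) for p in report.removed_correlated],
            "n_kept": report.n_kept,
        },
        split={"train_ids": split.train_ids, "test_ids": split.test_ids},
        best_model=best.model.to_dict(),
        ranked_models=[
            {"model": rm.model.to_dict(), "lof": rm.lof, "r2": rm.stats.r2}
            for rm in gfa.ranked_models[: config.top_k]
        ],
        internal=asdict(internal),
        external=asdict(external),
        diagnostics={
            "vif": diagnostics.vif.to_dict(),
            "mean_effect": diagnostics.mean_effect.to_dict(),
            "correlation": diagnostics.correlation.to_dict(),
        },
        domain={
            "warning_leverage": domain.warning_leverage,
            "outliers": [str(c) for c in domain.outliers],
            "high_leverage": [str(c) for c in domain.high_leverage],
        },
        criteria={
            "verdicts": criteria.verdicts,
            "not_evaluated": criteria.not_evaluated,
            "overall_pass": criteria.overall_pass,
        },
        screening=screening,
    )
    report_obj.to_json(out / "report.json")
    return report_obj


def reproduce_paper_tables() -> pd.DataFrame:
    """Recompute every statistic derivable from the packaged tables.

    Returns a frame of printed-vs-recomputed pairs with absolute
    differences: the model-1 predictions for the validation compounds, the
    external sums of squares and R^2_pred, the warning leverage, the
    adjusted R^2 implied by the printed training R^2, and the
    rule-of-five screen of the 18 designed compounds.
    """
    printed = datasets.PRINTED
    vset = datasets.load_validation_set()
    m1 = published_model(1)
    rows = []

    y_pred = m1.predict(vset)
    for cid in vset.index:
        rows.append((f"model1_pred_{cid}", vset.loc[cid, "y_pred_printed"],
                     float(y_pred[cid])))

    ext = external_r2pred(vset["pic50"], vset["y_pred_printed"],
                          printed["train_mean_pic50"])
    rows.append(("ss_res_test", printed["ss_res_test"], ext.ss_res))
    rows.append(("ss_tot_test", printed["ss_tot_test"], ext.ss_tot))
    rows.append(("r2_pred", printed["r2_pred"], ext.r2_pred))

    rows.append(("warning_leverage", printed["warning_leverage"],
                 round(warning_leverage(printed["n_descriptors"],
                                        printed["n_train"]), 2)))
    rows.append(("r2_adj", printed["r2_adj"],
                 adjusted_r2(printed["r2_train"], printed["n_train"],
                             printed["n_descriptors"])))

    profiles = read_property_table(
        datasets._path("designed_properties.csv").open())
    summary = screen_table(profiles)
    rows.append(("designed_with_ge2_violations", 0.0,
                 float(summary.n_failing_ro5)))

    df = pd.DataFrame(rows, columns=["quantity", "printed", "recomputed"])
    df["abs_diff"] = (df["printed"] - df["recomputed"]).abs()
    return df
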