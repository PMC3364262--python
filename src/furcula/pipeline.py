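"""Configuration-driven orchestration of the full analysis.

A :class:`RunConfig` points at an outline CSV, a metadata CSV (specimen,
flight mode or "unknown"), a Newick tree and optional node ages, and fixes
every stochastic choice through a mandatory seed.  ``run_extant_analysis``
covers the training-only chain (eigenshapes, signal tests, phylogenetic
(M)ANOVA and Tukey grids, optional mass regression); ``run_full_analysis``
refits eigenshapes on the combined extant + unknown sample — the
variation captured is maximized per taxon set rather than projecting
unknowns onto training axes — then optimizes lambda, trains the pFDA and
reports per-unknown predictions with a lambda-sweep stability score.

Every artifact is written as CSV (or JSON for the model and manifest) into
a bundle directory, with a plain-text log carrying a key=value header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import eigenshape as es
from . import pfda as pf
from .phylo import TimeTree, read_newick, scale_to_dates
from .phylo_signal import signal_report
from .phylo_tests import normality_diagnostics, phyl_anova, phyl_rma, phyl_tukey_hsd
from .shapes_io import DEFAULT_N_POINTS, orient_standard, read_outlines_csv, resample_equal_arclength

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"


@dataclass
class RunConfig:
    outlines: str
    metadata: str
    tree: str
    ages: str | None = None
    view: str = "profile"
    curve_definition: str = "inside"
    n_points: int = DEFAULT_N_POINTS
    retained_axes: int = 3
    n_perm: int = 999
    n_sim: int = 999
    lambda_grid_step: float = 0.01
    seed: int | None = None
    include_subaqueous: bool = False
    include_unknowns_in_lambda: bool = False
    branch_transform: bool = True
    use_correlation: bool = True
    mass_column: str | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.outlines, self.metadata, self.tree, self.ages):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        if text.lstrip().startswith("{"):
            data = json.loads(text)
        else:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                data[k.strip()] = v.strip()
        kwargs = {}
        for f_ in RunConfig.__dataclass_fields__.values():
            if f_.name not in data:
                continue
            v = data[f_.name]
            if isinstance(v, str):
                if f_.type in ("int", "int | None"):
                    v = int(v)
                elif f_.type == "float":
                    v = float(v)
                elif f_.type == "bool":
                    v = v.lower() in ("1", "true", "yes")
            kwargs[f_.name] = v
        return RunConfig(**kwargs)


def _load_inputs(config: RunConfig):
    curves = [
        c for c in read_outlines_csv(config.outlines, config.curve_definition)
        if c.view == config.view
    ]
    meta = pd.read_csv(config.metadata).set_index("specimen_id")
    tree = read_newick(config.tree)
    if config.ages is not None:
        tree = scale_to_dates(tree, pd.read_csv(config.ages))
    keep = [c.specimen_id for c in curves if c.specimen_id in meta.index]
    tree_ids = set(tree.tip_labels)
    keep = [k for k in keep if k in tree_ids]
    curves = [c for c in curves if c.specimen_id in set(keep)]
    return curves, meta, tree


def _fit_scores(curves, config: RunConfig):
    pls = [
        resample_equal_arclength(orient_standard(c), config.n_points) for c in curves
    ]
    model = es.extended_eigenshape_fit(pls, use_correlation=config.use_correlation)
    k = min(config.retained_axes, model.scores.shape[1])
    scores = pd.DataFrame(
        model.scores[:, :k],
        index=list(model.specimen_ids),
        columns=[f"es{i + 1}" for i in range(k)],
    )
    return model, scores


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format="%.12g", **kw)


def _ternary_coordinates(scores: pd.DataFrame) -> pd.DataFrame:
    """Min-max-rescaled |ES1..ES3| normalized to sum to 1 (for ternary plots)."""
    A = scores.iloc[:, :3].abs()
    A = (A - A.min()) / (A.max() - A.min()).replace(0, 1.0)
    s = A.sum(axis=1).replace(0, 1.0)
    out = A.div(s, axis=0)
    out.columns = [f"tern_{c}" for c in out.columns]
    return out


def run_extant_analysis(config: RunConfig, outdir: str | Path) -> dict:
    """Training-only analysis bundle; every specimen must carry a label."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _start_log(out, config, "extant")
    curves, meta, tree = _load_inputs(config)
    labels = meta["flight_mode"].reindex([c.specimen_id for c in curves])
    if (labels == UNKNOWN).any() or labels.isna().any():
        bad = list(labels.index[(labels == UNKNOWN) | labels.isna()])
        raise ValueError(f"unlabeled specimens in extant mode: {bad}")
    if not config.include_subaqueous:
        keep = labels[labels != "SUB"].index
        curves = [c for c in curves if c.specimen_id in set(keep)]
        labels = labels.loc[keep]
    sub = _prune(tree, list(labels.index))
    model, scores = _fit_scores(curves, config)
    scores = scores.reindex(sub.tip_labels)
    labels = labels.reindex(sub.tip_labels)

    _write(es.scores_table(model, config.retained_axes), out / "scores.csv", index=False)
    _write(es.variance_table(model), out / "variance.csv", index=False)
    es.save_model(model, out / "eigenshape_model.json")
    _write(_ternary_coordinates(scores), out / "ternary_coordinates.csv")

    sig = signal_report(scores, sub, n_perm=config.n_perm, seed=config.seed)
    _write(sig, out / "signal_tests.csv", index=False)

    manova = phyl_anova(scores, labels, sub, n_sim=config.n_sim, seed=config.seed)
    anova_rows = [
        {
            "trait": "+".join(scores.columns),
            "statistic_name": manova.statistic_name,
            "statistic": manova.statistic,
            "p_ahistorical": manova.p_ahistorical,
            "p_phylogenetic": manova.p_phylogenetic,
        }
    ]
    hsd_tables = {}
    for j, col in enumerate(scores.columns):
        r = phyl_anova(scores[col], labels, sub, n_sim=config.n_sim, seed=config.seed + j + 1)
        anova_rows.append(
            {
                "trait": col,
                "statistic_name": r.statistic_name,
                "statistic": r.statistic,
                "p_ahistorical": r.p_ahistorical,
                "p_phylogenetic": r.p_phylogenetic,
            }
        )
        hsd_tables[col] = phyl_tukey_hsd(
            scores[col], labels, sub, n_sim=config.n_sim, seed=config.seed + 100 + j
        )
    _write(pd.DataFrame(anova_rows), out / "anova.csv", index=False)
    for col, tbl in hsd_tables.items():
        _write(tbl, out / f"tukey_{col}.csv", index=False)

    diag = normality_diagnostics(scores, labels)
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=1))

    results = {"model": model, "scores": scores, "labels": labels, "tree": sub,
               "anova": anova_rows, "signal": sig}
    if config.mass_column and config.mass_column in meta.columns:
        mass = meta[config.mass_column].reindex(scores.index)
        rma = phyl_rma(mass, scores.iloc[:, 0], sub)
        (out / "rma_mass.json").write_text(json.dumps(rma, indent=1))
        results["rma"] = rma
    _manifest(out)
    return results


def run_full_analysis(config: RunConfig, outdir: str | Path) -> dict:
    """Combined extant + unknown analysis with pFDA predictions.

    Eigenshapes are refitted on the combined sample; unknowns (flight mode
    ``"unknown"``) are excluded from discriminant training but whitened
    jointly at prediction time.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _start_log(out, config, "full")
    curves, meta, tree = _load_inputs(config)
    labels_all = meta["flight_mode"].reindex([c.specimen_id for c in curves])
    unknown_ids = list(labels_all.index[(labels_all == UNKNOWN) | labels_all.isna()])
    train_labels = labels_all.drop(unknown_ids)
    if not config.include_subaqueous:
        train_labels = train_labels[train_labels != "SUB"]
    ids = list(train_labels.index) + unknown_ids
    curves = [c for c in curves if c.specimen_id in set(ids)]
    missing = [u for u in unknown_ids if u not in set(tree.tip_labels)]
    if missing:
        raise ValueError(f"unknown tips absent from tree: {missing}")
    sub = _prune(tree, ids)

    model, scores = _fit_scores(curves, config)
    _write(es.scores_table(model, config.retained_axes), out / "scores_full.csv", index=False)
    _write(es.variance_table(model), out / "variance_full.csv", index=False)
    _write(_ternary_coordinates(scores), out / "ternary_coordinates_full.csv")

    train_scores = scores.loc[train_labels.index]
    if config.include_unknowns_in_lambda:
        lam, profile, flat = pf.optimize_lambda(train_scores, train_labels, sub)
    else:
        lam, profile, flat = pf.optimize_lambda(
            train_scores, train_labels, _prune(sub, list(train_labels.index))
        )
    _write(profile, out / "lambda_profile.csv", index=False)
    pmodel = pf.pfda_train(train_scores, train_labels, sub, lam=lam)
    resub = pf.pfda_predict(pmodel, train_scores, sub)
    cm = pf.confusion_summary(
        train_labels.reindex(resub.index), resub["predicted"], classes=pmodel.classes
    )
    cm_out = cm.counts.copy()
    cm_out.loc["% Correct"] = [f"{v}%" for v in cm.percent_correct]
    _write(cm_out, out / "confusion_training.csv")
    _write(pmodel.discriminant_coordinates(), out / "discriminant_coordinates.csv")

    pred = pf.pfda_predict(pmodel, scores.loc[unknown_ids], sub) if unknown_ids else None
    if pred is not None:
        _write(pred, out / "predictions_unknown.csv")
        sweep, stability = pf.lambda_sweep(
            train_scores, train_labels, scores.loc[unknown_ids], sub
        )
        sweep_out = sweep.copy()
        sweep_out["stability"] = stability
        _write(sweep_out, out / "lambda_sweep.csv")
    _manifest(out)
    return {
        "model": model,
        "scores": scores,
        "pfda": pmodel,
        "lambda": lam,
        "flat_profile": flat,
        "confusion": cm,
        "predictions": pred,
    }


def _prune(tree: TimeTree, tips: list[str]) -> TimeTree:
    if set(tips) == set(tree.tip_labels):
        return tree
    sub = tree.copy()
    sub.tree.retain_taxa_with_labels(tips)
    return TimeTree(sub.tree)


def _start_log(out: Path, config: RunConfig, mode: str) -> None:
    header = [f"mode={mode}"] + [f"{k}={v}" for k, v in asdict(config).items()]
    (out / "run.log").write_text("\n".join(header) + "\n", encoding="utf-8")


def _manifest(out: Path) -> None:
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    (out / "manifest.json").write_text(json.dumps({"files": files}, indent=1))
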