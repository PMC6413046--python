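"""Full-analysis orchestration: per-descriptor and integrated PLS models,
outlier elimination, BOSS variable selection, and report tables.

The FTC route compares models before/after MPA outlier elimination; the FRAP
route compares models before/after the log transform of the response (and
additionally checks the integrated data for outliers).  Reports are emitted
as machine-readable JSON plus a human-readable text table with Q2/R2 to four
decimals.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .boss import BossAggregate, boss_aggregate, top_variables
from .datasets import load_frap, load_ftc, load_peptide_table
from .outliers import eliminate_outliers
from .pls import CVScheme, cross_validate, select_components
from .scales import REGISTRY_ORDER, all_scales, encode_dataset, get_scale


@dataclass
class AnalysisConfig:
    dataset: str = "ftc"                      # "ftc", "frap" or a file path
    scales: Optional[Sequence[str]] = None    # None = full 16-scale registry
    cv: CVScheme = field(default_factory=CVScheme)
    seed: int = 1
    n_sub: int = 1000
    n_runs: int = 100
    max_components: int = 20
    boss_threshold: int = 75
    stages: Sequence[str] = ("encode", "pls", "outliers", "boss")
    out_dir: Optional[str] = None

    def scale_names(self) -> list[str]:
        return list(self.scales) if self.scales else list(REGISTRY_ORDER)


@dataclass
class DescriptorRow:
    descriptor: str
    q2_before: float
    r2_before: float
    optpc_before: int
    q2_after: Optional[float] = None
    r2_after: Optional[float] = None
    optpc_after: Optional[int] = None
    outliers_removed: Optional[list] = None


@dataclass
class AnalysisReport:
    dataset: str
    treatment: str
    per_descriptor: list[DescriptorRow]
    integrated: Optional[DescriptorRow] = None
    boss: Optional[dict] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "treatment": self.treatment,
            "per_descriptor": [asdict(r) for r in self.per_descriptor],
            "integrated": None if self.integrated is None
            else asdict(self.integrated),
            "boss": self.boss,
            "provenance": self.provenance,
        }

    def to_text(self) -> str:
        hdr = (f"{'descriptor':<22}{'Q2':>9}{'R2':>9}{'optPC':>7}"
               f"{'Q2*':>9}{'R2*':>9}{'optPC*':>8}  outliers")
        lines = [f"dataset: {self.dataset}   (*) after {self.treatment}", hdr]

        def fmt(v, width, dec=4):
            return " " * width if v is None else f"{v:>{width}.{dec}f}"

        def fmti(v, width):
            return " " * width if v is None else f"{v:>{width}d}"

        rows = list(self.per_descriptor)
        if self.integrated is not None:
            rows.append(self.integrated)
        for r in rows:
            out = "" if r.outliers_removed is None else \
                ", ".join(str(o) for o in r.outliers_removed)
            lines.append(
                f"{r.descriptor:<22}{fmt(r.q2_before, 9)}{fmt(r.r2_before, 9)}"
                f"{fmti(r.optpc_before, 7)}{fmt(r.q2_after, 9)}"
                f"{fmt(r.r2_after, 9)}{fmti(r.optpc_after, 8)}  {out}"
            )
        if self.boss is not None:
            lines.append(
                f"{'BOSS':<22}Q2 {self.boss['q2_mean']:.4f} +/- "
                f"{self.boss['q2_sd']:.4f}   R2 {self.boss['r2_mean']:.4f} "
                f"+/- {self.boss['r2_sd']:.4f}   optPC "
                f"{self.boss['optpc_mean']:.2f} +/- {self.boss['optpc_sd']:.2f}"
            )
            lines.append("top variables (freq > threshold): "
                         + ", ".join(self.boss["top_variables"]))
        return "\n".join(lines)


def _model_stats(X, y, cv, cmax):
    """(q2, r2, optpc) for one encoding: CV curve + training fit."""
    from .pls import fit_pls

    q2_curve = cross_validate(X, y, cv, cmax)
    opt = select_components(q2_curve)
    fitted = fit_pls(X, y, opt)
    return float(q2_curve[opt - 1]), float(fitted.r2), opt


def _boss_summary(agg: BossAggregate, threshold: int) -> dict:
    return {
        "n_runs": agg.n_runs,
        "q2_mean": agg.q2_mean, "q2_sd": agg.q2_sd,
        "r2_mean": agg.r2_mean, "r2_sd": agg.r2_sd,
        "optpc_mean": agg.optpc_mean, "optpc_sd": agg.optpc_sd,
        "threshold": threshold,
        "top_variables": top_variables(agg, threshold),
        "frequency": agg.frequency,
    }


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the configured stages and build the report."""
    names = config.scale_names()
    cv, cmax = config.cv, config.max_components
    want = set(config.stages)
    if config.dataset == "ftc":
        ds = load_ftc()
        treatment = "outlier elimination"
    elif config.dataset == "frap":
        ds = load_frap(drop_inactive=True)
        treatment = "log transform"
    else:
        ds = load_peptide_table(config.dataset, name=Path(config.dataset).stem)
        treatment = "outlier elimination"

    rows = []
    integrated_row = None
    boss_summary = None
    y = ds.activities
    y_raw = 10.0 ** y if config.dataset == "frap" else None

    def encode_with(scale_names):
        return encode_dataset(
            ds.sequences, y, [get_scale(s) for s in scale_names],
            sample_ids=ds.row_numbers,
        )

    cleaned_integrated = None
    if "pls" in want:
        for name in names:
            enc = encode_with([name])
            if config.dataset == "frap":
                # before = raw activities, after = log-transformed
                q2b, r2b, pcb = _model_stats(enc.X, y_raw, cv, cmax)
                q2a, r2a, pca = _model_stats(enc.X, y, cv, cmax)
                rows.append(DescriptorRow(name, q2b, r2b, pcb, q2a, r2a, pca))
            else:
                q2b, r2b, pcb = _model_stats(enc.X, enc.y, cv, cmax)
                row = DescriptorRow(name, q2b, r2b, pcb)
                if "outliers" in want:
                    rep = eliminate_outliers(
                        enc, n_sub=config.n_sub, seed=config.seed, cv=cv,
                        max_components=cmax,
                    )
                    fin = rep.final_dataset
                    row.q2_after, row.r2_after, row.optpc_after = _model_stats(
                        fin.X, fin.y, cv, cmax
                    )
                    row.outliers_removed = rep.removed_sequence
                rows.append(row)

        enc = encode_with(names)
        if config.dataset == "frap":
            q2b, r2b, pcb = _model_stats(enc.X, y_raw, cv, cmax)
            q2a, r2a, pca = _model_stats(enc.X, y, cv, cmax)
            integrated_row = DescriptorRow(
                "Integrated descriptors", q2b, r2b, pcb, q2a, r2a, pca
            )
            cleaned_integrated = enc
            if "outliers" in want:
                rep = eliminate_outliers(
                    enc, n_sub=config.n_sub, seed=config.seed, cv=cv,
                    max_components=cmax,
                )
                integrated_row.outliers_removed = rep.removed_sequence
                cleaned_integrated = rep.final_dataset
        else:
            q2b, r2b, pcb = _model_stats(enc.X, enc.y, cv, cmax)
            integrated_row = DescriptorRow(
                "Integrated descriptors", q2b, r2b, pcb
            )
            cleaned_integrated = enc
            if "outliers" in want:
                rep = eliminate_outliers(
                    enc, n_sub=config.n_sub, seed=config.seed, cv=cv,
                    max_components=cmax,
                )
                fin = rep.final_dataset
                (integrated_row.q2_after, integrated_row.r2_after,
                 integrated_row.optpc_after) = _model_stats(
                    fin.X, fin.y, cv, cmax
                )
                integrated_row.outliers_removed = rep.removed_sequence
                cleaned_integrated = fin

    if "boss" in want and cleaned_integrated is not None:
        agg = boss_aggregate(
            cleaned_integrated, n_runs=config.n_runs, n_sub=config.n_sub,
            base_seed=config.seed, cv=cv, max_components=cmax,
        )
        boss_summary = _boss_summary(agg, config.boss_threshold)

    report = AnalysisReport(
        dataset=ds.name.lower(),
        treatment=treatment,
        per_descriptor=rows,
        integrated=integrated_row,
        boss=boss_summary,
        provenance={
            "version": __version__,
            "seed": config.seed,
            "cv": asdict(cv),
            "n_sub": config.n_sub,
            "n_runs": config.n_runs,
            "scales": names,
            "stages": list(config.stages),
        },
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"report_{report.dataset}.json").write_text(
            json.dumps(report.to_dict(), indent=1, default=_jsonable) + "\n"
        )
        (out / f"report_{report.dataset}.txt").write_text(
            report.to_text() + "\n"
        )
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
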