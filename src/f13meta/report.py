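"""Full meta-analysis orchestration and table export.

:func:`run_meta` runs every genetic model through the whole chain —
contingency tables, per-study effects, heterogeneity, pooled odds ratio
(method chosen by policy), leave-one-out sensitivity, and publication-bias
tests — and returns a :class:`MetaReport`. :func:`export_report` writes the
report as a set of tidy CSV tables plus forest/funnel coordinate files;
re-exporting the same report is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import pooling
from .bias import BiasTestResult, bias_tests, funnel_coordinates
from .genetic_models import (ContingencyTable, Exclusion, GeneticModel,
                             derive_all)
from .hwe import HweResult, hwe_chi_square
from .pooling import PooledResult, heterogeneity, select_method
from .sensitivity import LeaveOneOutResult, leave_one_out
from .study_io import StudySet

POLICIES = ("auto", "force_fixed", "force_random")


@dataclass(frozen=True)
class ModelBlock:
    """Everything computed for one genetic model."""

    model: GeneticModel
    tables: tuple[ContingencyTable, ...]
    exclusions: tuple[Exclusion, ...]
    effects: tuple[pooling.EffectEstimate, ...]
    method: str
    pooled: PooledResult
    loo: Optional[LeaveOneOutResult]       # None when k < 2
    bias: Optional[BiasTestResult]         # None when k < 3


@dataclass(frozen=True)
class MetaReport:
    disease: str
    policy: str
    blocks: tuple[ModelBlock, ...]         # one per genetic model, fixed order
    hwe: tuple[tuple[str, Optional[HweResult]], ...]  # per study; None = carrier-only

    def block(self, model: GeneticModel) -> ModelBlock:
        model = GeneticModel(model)
        for b in self.blocks:
            if b.model is model:
                return b
        raise KeyError(model)


def run_meta(studies: StudySet, policy: str = "auto",
             i2_threshold: float = 50.0) -> MetaReport:
    """Run the five-model meta-analysis on one study set.

    ``policy`` decides fixed vs random effects: ``auto`` applies
    :func:`~f13meta.pooling.select_method` to the I^2 of each model,
    ``force_fixed``/``force_random`` pin the method for every model.
    """
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")

    hwe_rows = []
    for s in studies:
        if s.carrier_only:
            hwe_rows.append((s.study_id, None))
        else:
            hwe_rows.append((s.study_id, hwe_chi_square(*s.genotype_counts("controls"))))

    blocks = []
    for model in GeneticModel:
        tables, exclusions = derive_all(studies, model)
        effects = tuple(pooling.study_effect(t) for t in tables)
        if policy == "force_fixed":
            method = pooling.MH_FIXED
        elif policy == "force_random":
            method = pooling.DL_RANDOM
        else:
            het = (heterogeneity(effects) if len(effects) >= 2
                   else pooling._het_from_effects(effects))
            method = select_method(het, i2_threshold)
        pooled = pooling.pool(tables, method)
        loo = leave_one_out(tables, method) if len(tables) >= 2 else None
        bias = bias_tests(effects) if len(effects) >= 3 else None
        blocks.append(ModelBlock(
            model=model, tables=tables, exclusions=tuple(exclusions),
            effects=effects, method=method, pooled=pooled, loo=loo, bias=bias,
        ))
    return MetaReport(disease=studies.disease, policy=policy,
                      blocks=tuple(blocks), hwe=tuple(hwe_rows))


def _f(x: Optional[float]) -> str:
    """Stable float formatting so re-exports are byte-identical."""
    return "" if x is None else format(x, ".6g")


def export_report(report: MetaReport, out_dir) -> list[Path]:
    """Write the report tables to ``out_dir``; returns the paths written.

    Files: pooled.csv, hwe.csv, sensitivity.csv, bias.csv, exclusions.txt,
    forest.csv, funnel.csv. Bias rows for models with fewer than three
    studies carry ``NC`` (not computed) markers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    pooled_rows = []
    for b in report.blocks:
        p = b.pooled
        pooled_rows.append({
            "disease": report.disease, "model": b.model.value, "k": p.k,
            "method": p.method, "pooled_or": _f(p.pooled_or),
            "ci_low": _f(p.ci_low), "ci_high": _f(p.ci_high),
            "z": _f(p.z), "p": _f(p.p), "q": _f(p.het.q), "df": p.het.df,
            "p_q": _f(p.het.p_q), "i2_pct": _f(p.het.i2), "tau2": _f(p.het.tau2),
            "significant": p.significant,
        })
    written.append(_write_csv(pd.DataFrame(pooled_rows), out / "pooled.csv"))

    hwe_rows = []
    for study_id, res in report.hwe:
        hwe_rows.append({
            "disease": report.disease, "study_id": study_id,
            "chi2": _f(res.chi2) if res else "NC",
            "p": _f(res.p_value) if res else "NC",
            "leu_freq": _f(res.allele_freq_leu) if res else "NC",
            "in_equilibrium": res.in_equilibrium if res else "NC",
        })
    written.append(_write_csv(pd.DataFrame(hwe_rows), out / "hwe.csv"))

    sens_rows = []
    for b in report.blocks:
        if b.loo is None:
            continue
        for r in b.loo.rows:
            sens_rows.append({
                "disease": report.disease, "model": b.model.value,
                "method": b.loo.method, "omitted_study": r.omitted_study,
                "pooled_or": _f(r.pooled_or), "ci_low": _f(r.ci_low),
                "ci_high": _f(r.ci_high), "p": _f(r.p),
                "significant": r.significant, "verdict_stable": b.loo.stable,
            })
    written.append(_write_csv(pd.DataFrame(sens_rows), out / "sensitivity.csv"))

    bias_rows = []
    for b in report.blocks:
        t = b.bias
        bias_rows.append({
            "disease": report.disease, "model": b.model.value,
            "k": t.k if t else len(b.effects),
            "egger_intercept": _f(t.egger_intercept) if t else "NC",
            "egger_ci_low": _f(t.egger_ci_low) if t else "NC",
            "egger_ci_high": _f(t.egger_ci_high) if t else "NC",
            "egger_p": _f(t.egger_p) if t else "NC",
            "begg_tau": _f(t.begg_tau) if t else "NC",
            "begg_p": _f(t.begg_p) if t else "NC",
            "begg_p_corrected": _f(t.begg_p_corrected) if t else "NC",
        })
    written.append(_write_csv(pd.DataFrame(bias_rows), out / "bias.csv"))

    lines = []
    for b in report.blocks:
        for e in b.exclusions:
            lines.append(f"{b.model.value}: {e.study_id} — {e.reason}")
    (out / "exclusions.txt").write_text(
        "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    written.append(out / "exclusions.txt")

    forest_rows = []
    for b in report.blocks:
        weights = dict(b.pooled.weights)
        for e in b.effects:
            forest_rows.append({
                "disease": report.disease, "model": b.model.value,
                "study_id": e.study_id, "or": _f(e.or_),
                "ci_low": _f(e.ci_low), "ci_high": _f(e.ci_high),
                "weight_pct": _f(weights[e.study_id]),
            })
    written.append(_write_csv(pd.DataFrame(forest_rows), out / "forest.csv"))

    funnel_rows = []
    for b in report.blocks:
        fd = funnel_coordinates(b.effects)
        for _, row in fd.points.iterrows():
            funnel_rows.append({
                "disease": report.disease, "model": b.model.value,
                "study_id": row["study_id"], "log_or": _f(row["log_or"]),
                "se": _f(row["se"]), "center_log_or": _f(fd.center_log_or),
            })
    written.append(_write_csv(pd.DataFrame(funnel_rows), out / "funnel.csv"))
    return written


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.write_text(df.to_csv(index=False, lineterminator="\n"), encoding="utf-8")
    return path
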