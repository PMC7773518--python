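"""End-to-end SOT validation analysis.

Orchestrates the full comparison between an Equitest session and its VR
counterpart:

1. keep only the final trial per (participant, condition, device) — the
   first trial of each condition is familiarization;
2. condition the VR COP traces and compute the four balance metrics;
3. pair Equitest equilibrium-index scores with VR-derived scores per SOT
   condition;
4. screen primary scores per device-condition with a single-pass 3-SD
   rule, removing a flagged participant's whole pair in that condition;
5. compute the agreement panel (ICCs, Pearson, Bland-Altman) between EI
   and eEI, plus Pearson correlations of EI against each COP metric;
6. optionally write a results CSV, an exclusion log, and Bland-Altman /
   boxplot figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .agreement import (
    AgreementResult,
    PairedScores,
    analyze_pairs,
    pearson,
)
from .conditions import CONDITIONS, ConditionSpec
from .cop_io import SOT_CONDITIONS, Study, TrialRecord
from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError
from .metrics import DfaConfig, EiParams, compute_metrics
from .preprocess import PreprocessConfig, preprocess

__all__ = [
    "PipelineConfig",
    "ExclusionRecord",
    "ConditionResults",
    "select_analysis_trials",
    "exclude_outliers",
    "run_pipeline",
    "results_frame",
]

#: COP-derived measures correlated against the Equitest EI, in report order.
METRIC_COLUMNS = ("eei", "ellipse_area_95", "path_length", "dfa_alpha_ap")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the analysis, grouped by stage."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ei: EiParams = field(default_factory=EiParams)
    dfa: DfaConfig = field(default_factory=DfaConfig)
    outlier_sd: float = 3.0
    ba_multiplier: float = 1.96

    def __post_init__(self) -> None:
        if not self.outlier_sd > 0:
            raise ValidationError("outlier_sd must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Build a config from a YAML file with optional sections
        ``preprocess``, ``ei``, ``dfa`` and top-level scalars."""
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            preprocess=PreprocessConfig(**doc.get("preprocess", {})),
            ei=EiParams(**doc.get("ei", {})),
            dfa=DfaConfig(**doc.get("dfa", {})),
            outlier_sd=float(doc.get("outlier_sd", 3.0)),
            ba_multiplier=float(doc.get("ba_multiplier", 1.96)),
        )


@dataclass(frozen=True)
class ExclusionRecord:
    """Why one participant's pair was dropped from one condition."""

    pid: str
    condition: str
    device: str
    score: float
    cond_mean: float
    cond_sd: float

    def __str__(self) -> str:
        return (
            f"{self.condition} {self.pid}: {self.device} score "
            f"{self.score:.3f} outside mean {self.cond_mean:.3f} "
            f"+/- 3 x SD {self.cond_sd:.3f}; pair removed"
        )


@dataclass(frozen=True)
class ConditionResults:
    """Agreement panel and EI-vs-metric correlations for one condition.

    ``agreement`` and entries of ``correlations`` are None when too few
    valid pairs remain to compute them.
    """

    condition: ConditionSpec
    n_retained: int
    agreement: AgreementResult | None
    correlations: dict[str, tuple[float, float] | None]


def select_analysis_trials(
    study: Study,
) -> dict[tuple[str, str, str], TrialRecord]:
    """Final trial per (pid, condition, device); earlier trials discarded."""
    selected: dict[tuple[str, str, str], TrialRecord] = {}
    for tr in study.trials:
        key = (tr.pid, tr.condition, tr.device)
        cur = selected.get(key)
        if cur is None or tr.trial_index > cur.trial_index:
            selected[key] = tr
    return selected


def _condition_scores(
    study: Study, cfg: PipelineConfig, condition: str
) -> pd.DataFrame:
    """Paired per-participant table for one condition.

    Columns: pid, ei (Equitest) and the four VR COP metrics.  Participants
    lacking either device's final trial are omitted.
    """
    selected = select_analysis_trials(study)
    rows = []
    for pid in sorted(study.participants):
        eq = selected.get((pid, condition, "equitest"))
        vr = selected.get((pid, condition, "vr"))
        if eq is None or vr is None:
            continue
        trace = preprocess(vr.trace, cfg.preprocess)
        m = compute_metrics(trace, study.participants[pid].height, cfg.ei, cfg.dfa)
        rows.append(
            {
                "pid": pid,
                "ei": float(eq.ei),
                "eei": m.eei,
                "ellipse_area_95": m.ellipse_area_95,
                "path_length": m.path_length,
                "dfa_alpha_ap": m.dfa_alpha_ap,
            }
        )
    return pd.DataFrame(rows, columns=["pid", "ei", *METRIC_COLUMNS])


def exclude_outliers(
    scores: pd.DataFrame, sd_threshold: float = 3.0, condition: str = "?"
) -> tuple[pd.DataFrame, list[ExclusionRecord]]:
    """Single-pass 3-SD screen on the primary scores of one condition.

    The mean and SD of each device's score vector (``ei`` for Equitest,
    ``eei`` for VR) are computed once from the full vector; any entry more
    than ``sd_threshold`` SDs from its device-condition mean removes that
    participant's whole pair.  Vectors shorter than 3 are left unscreened.
    """
    if scores.empty or len(scores) < 3:
        return scores.copy(), []
    flags: dict[str, ExclusionRecord] = {}
    for device, col in (("equitest", "ei"), ("vr", "eei")):
        vec = scores[col].to_numpy(dtype=float)
        mean = float(np.mean(vec))
        sd = float(np.std(vec, ddof=1))
        if sd == 0.0:
            continue
        for pid, val in zip(scores["pid"], vec):
            if abs(val - mean) > sd_threshold * sd and pid not in flags:
                flags[pid] = ExclusionRecord(
                    pid=pid, condition=condition, device=device,
                    score=float(val), cond_mean=mean, cond_sd=sd,
                )
    kept = scores[~scores["pid"].isin(flags)].reset_index(drop=True)
    return kept, [flags[pid] for pid in sorted(flags)]


def _metric_correlations(
    table: pd.DataFrame, condition: str
) -> dict[str, tuple[float, float] | None]:
    out: dict[str, tuple[float, float] | None] = {}
    for col in METRIC_COLUMNS:
        sub = table[["pid", "ei", col]].dropna()
        if len(sub) < 3:
            warnings.warn(
                f"{condition}: fewer than 3 valid pairs for {col}; correlation skipped"
            )
            out[col] = None
            continue
        pairs = PairedScores(
            pids=tuple(sub["pid"]),
            x=sub["ei"].to_numpy(),
            y=sub[col].to_numpy(),
        )
        try:
            out[col] = pearson(pairs)
        except (UndefinedStatisticError, InsufficientDataError) as exc:
            warnings.warn(f"{condition}: correlation with {col} undefined ({exc})")
            out[col] = None
    return out


def run_pipeline(
    study: Study,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    plots: bool = False,
) -> list[ConditionResults]:
    """Run the full per-condition analysis over a paired study.

    Returns one :class:`ConditionResults` per SOT condition, in protocol
    order.  With ``outdir`` set, also writes ``results.csv``,
    ``exclusions.log`` and (with ``plots=True``) a ``figures/`` directory.
    """
    cfg = cfg or PipelineConfig()
    results: list[ConditionResults] = []
    all_exclusions: list[ExclusionRecord] = []
    tables: dict[str, pd.DataFrame] = {}

    for condition in SOT_CONDITIONS:
        table = _condition_scores(study, cfg, condition)
        table, excluded = exclude_outliers(table, cfg.outlier_sd, condition)
        all_exclusions.extend(excluded)
        tables[condition] = table

        agreement: AgreementResult | None = None
        if len(table) >= 3:
            pairs = PairedScores(
                pids=tuple(table["pid"]),
                x=table["ei"].to_numpy(),
                y=table["eei"].to_numpy(),
            )
            try:
                agreement = analyze_pairs(pairs, ba_multiplier=cfg.ba_multiplier)
            except (UndefinedStatisticError, InsufficientDataError) as exc:
                warnings.warn(f"{condition}: agreement undefined ({exc})")
        else:
            warnings.warn(
                f"{condition}: only {len(table)} paired participant(s); "
                "agreement statistics skipped"
            )
        correlations = _metric_correlations(table, condition)
        results.append(
            ConditionResults(
                condition=CONDITIONS[condition],
                n_retained=len(table),
                agreement=agreement,
                correlations=correlations,
            )
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results_frame(results).to_csv(
            outdir / "results.csv", index=False, float_format="%.10g"
        )
        (outdir / "exclusions.log").write_text(
            "".join(f"{rec}\n" for rec in all_exclusions)
        )
        if plots:
            from .plots import bland_altman_grid, condition_boxplots

            figdir = outdir / "figures"
            figdir.mkdir(exist_ok=True)
            bland_altman_grid(tables, cfg.ba_multiplier, figdir / "bland_altman.png")
            condition_boxplots(tables, figdir / "boxplots.png")
    return results


def results_frame(results: list[ConditionResults]) -> pd.DataFrame:
    """Flatten per-condition results into one row per condition."""
    rows = []
    for res in results:
        row: dict = {"condition": res.condition.code, "n_retained": res.n_retained}
        a = res.agreement
        row.update(
            icc_absolute=a.icc_absolute if a else np.nan,
            icc_consistency=a.icc_consistency if a else np.nan,
            icc_label=a.icc_label if a else "",
            ba_mean_diff=a.ba_mean_diff if a else np.nan,
            ba_loa_low=a.ba_loa_low if a else np.nan,
            ba_loa_high=a.ba_loa_high if a else np.nan,
        )
        for col in METRIC_COLUMNS:
            rp = res.correlations.get(col)
            row[f"r_{col}"] = rp[0] if rp else np.nan
            row[f"p_{col}"] = rp[1] if rp else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def format_results_table(results: list[ConditionResults]) -> pd.DataFrame:
    """Report-style table: r to 3 decimals, p to 3 decimals."""
    df = results_frame(results)
    out = df[["condition", "n_retained"]].copy()
    for col in ("icc_absolute", "icc_consistency"):
        out[col] = df[col].round(3)
    for col in METRIC_COLUMNS:
        out[f"r_{col}"] = df[f"r_{col}"].round(3)
        out[f"p_{col}"] = df[f"p_{col}"].round(3)
    return out
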