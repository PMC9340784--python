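"""Group statistics, significance stars, qPCR normalization, phase tables.

Group comparisons use the classic pooled-variance Student's t-test (Welch
available as an option), reported as means with standard errors and a
significance star string. Relative transcript abundance is computed from
qPCR cycle thresholds as 2^(-dCt) against the EF1-alpha reference gene.
Mitosis-figure tallies (from H3S10p immunostaining) are converted to
relative frequencies per phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "MITOSIS_PHASES",
    "GroupSample",
    "ComparisonResult",
    "ExpressionRecord",
    "mean_sem",
    "t_test",
    "stars",
    "relative_expression",
    "expression_table",
    "phase_frequencies",
    "adjust_pvalues",
]

#: Mitotic figures distinguished on H3S10p-stained sections.
MITOSIS_PHASES = (
    "G2",
    "early prophase",
    "late prophase",
    "prometaphase/metaphase",
    "anaphase",
    "telophase",
)

#: Reference (housekeeping) gene for qPCR normalization.
REFERENCE_GENE = "EF1a"

# Star thresholds, strictest first; probed from the most stringent level
# down, so e.g. p = 0.0007 maps to '**'.
_STAR_LEVELS = ((1e-4, "****"), (5e-4, "***"), (1e-3, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GroupSample:
    """Per-animal values of one metric for one (ploidy class, stage) group."""

    label: tuple[str, int]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("GroupSample requires at least one value")
        if any(v is None or not math.isfinite(v) for v in self.values):
            raise ValueError("GroupSample values must be finite")


@dataclass(frozen=True)
class ComparisonResult:
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str
    degenerate_flag: bool = False


@dataclass(frozen=True)
class ExpressionRecord:
    sample_id: str
    target_gene: str
    ct_target: float
    ct_reference: float
    relative_expression: float


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sd with n-1 denominator over sqrt(n)).

    The SEM of a single observation is undefined, so n = 1 (and n = 0) is
    an error rather than a silent zero.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sem requires at least one value")
    if arr.size == 1:
        raise ValueError("SEM is undefined for a single value")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


def stars(p: float) -> str:
    """Significance stars: **** p<0.0001, *** p<0.0005, ** p<0.001, * p<0.05."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    for threshold, symbol in _STAR_LEVELS:
        if p < threshold:
            return symbol
    return "ns"


def t_test(a: GroupSample, b: GroupSample, welch: bool = False) -> ComparisonResult:
    """Two-sample Student's t-test (pooled variance; Welch optional).

    Two-sided p from the t distribution with n_a + n_b - 2 degrees of
    freedom (Welch-Satterthwaite when ``welch``). When both groups have
    zero variance the statistic is degenerate: equal means give t = 0,
    p = 1; unequal means give infinite t, p = 0 — flagged either way.
    """
    xa = np.asarray(a.values, dtype=float)
    xb = np.asarray(b.values, dtype=float)
    na, nb = xa.size, xb.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two values")
    ma, mb = float(xa.mean()), float(xb.mean())
    va, vb = float(xa.var(ddof=1)), float(xb.var(ddof=1))
    degenerate = va == 0.0 and vb == 0.0
    if welch:
        se2 = va / na + vb / nb
        df = (se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
              if se2 > 0 else float(na + nb - 2))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = float(na + nb - 2)
    if se2 == 0.0:
        t_stat = 0.0 if ma == mb else math.copysign(math.inf, ma - mb)
        p = 1.0 if ma == mb else 0.0
    else:
        t_stat = (ma - mb) / math.sqrt(se2)
        p = 2.0 * float(sstats.t.sf(abs(t_stat), df))
    return ComparisonResult(
        mean_a=ma,
        mean_b=mb,
        sem_a=math.sqrt(va / na),
        sem_b=math.sqrt(vb / nb),
        t_statistic=float(t_stat),
        degrees_of_freedom=df,
        p_value=min(p, 1.0),
        stars=stars(min(p, 1.0)),
        degenerate_flag=degenerate,
    )


def relative_expression(
    ct_target: float, ct_reference: float, calibrator_delta: Optional[float] = None
) -> float:
    """Relative expression 2^-(Ct_target - Ct_reference).

    One qPCR cycle is a two-fold change, so a target one cycle later than
    the reference is at half its abundance. With ``calibrator_delta`` the
    delta-delta-Ct variant 2^-(dCt - dCt_calibrator) is returned instead.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    dct = ct_target - ct_reference
    if calibrator_delta is not None:
        dct -= calibrator_delta
    return 2.0 ** (-dct)


def expression_table(ct_df, reference_gene: str = REFERENCE_GENE) -> list[ExpressionRecord]:
    """Build expression records from a tidy Ct table.

    ``ct_df`` is a DataFrame with columns sample_id, gene, ct; every
    sample must include the reference gene.
    """
    records = []
    for sample_id, grp in ct_df.groupby("sample_id", sort=True):
        ref_rows = grp[grp["gene"] == reference_gene]
        if ref_rows.empty:
            raise ValueError(f"sample {sample_id!r} lacks reference gene {reference_gene!r}")
        ct_ref = float(ref_rows["ct"].iloc[0])
        for _, row in grp[grp["gene"] != reference_gene].iterrows():
            ct_t = float(row["ct"])
            records.append(
                ExpressionRecord(
                    sample_id=str(sample_id),
                    target_gene=str(row["gene"]),
                    ct_target=ct_t,
                    ct_reference=ct_ref,
                    relative_expression=relative_expression(ct_t, ct_ref),
                )
            )
    return records


def adjust_pvalues(p_values: Sequence[float], method: str = "none") -> list[float]:
    """Optional multiple-testing correction for a family of comparisons.

    ``method``: 'none' (the default — pairwise tests are reported
    uncorrected), 'bonferroni', or 'bh' (Benjamini-Hochberg).
    """
    ps = np.asarray(p_values, dtype=float)
    if ps.size and (ps.min() < 0 or ps.max() > 1):
        raise ValueError("p-values must be in [0, 1]")
    if method == "none":
        return [float(p) for p in ps]
    if method == "bonferroni":
        return [float(min(p * ps.size, 1.0)) for p in ps]
    if method == "bh":
        return [float(p) for p in sstats.false_discovery_control(ps, method="bh")]
    raise ValueError(f"unknown correction method {method!r}")


def phase_frequencies(counts: Mapping[str, int]) -> dict[str, float]:
    """Relative frequency (percent) of each mitotic figure.

    Unknown phase names are rejected; percents sum to 100.
    """
    for phase in counts:
        if phase not in MITOSIS_PHASES:
            raise ValueError(f"unknown mitosis phase {phase!r}")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("total count must be positive")
    return {phase: 100.0 * counts.get(phase, 0) / total for phase in MITOSIS_PHASES}
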