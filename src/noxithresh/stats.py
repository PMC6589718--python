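"""First-principles inferential statistics for the simulated cohorts.

Implements the paired t-test with Cohen's d_z, the 2x2 fully within-subject
ANOVA with partial eta squared, the noncentral-t power computation behind the
paired-design sample size, and a descriptive confidence cross-tabulation.
The sums of squares are computed from their definitional forms rather than
delegated to a stats library, so they can be cross-checked against
independent implementations in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateSampleError(ValueError):
    """The sample admits no test statistic (e.g. zero-variance differences)."""


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p_two_sided: float
    dz: float
    mean_diff: float
    n: int


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired-samples t-test with Cohen's d_z.

    ``t = mean(d) / (sd(d)/sqrt(n))`` and ``dz = mean(d)/sd(d)`` for the
    differences ``d = x - y`` (sample sd, n-1 denominator), so ``t = dz*sqrt(n)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing pairs are not allowed")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            # all differences identically zero: define t = 0, p = 1
            return PairedTResult(t=0.0, df=n - 1, p_two_sided=1.0, dz=0.0,
                                 mean_diff=0.0, n=n)
        raise DegenerateSampleError("zero variance of nonzero differences")
    dz = d.mean() / sd
    t = dz * np.sqrt(n)
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTResult(t=float(t), df=n - 1, p_two_sided=float(p),
                         dz=float(dz), mean_diff=float(d.mean()), n=n)


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class AnovaResult:
    effects: dict[str, AnovaEffect]  # keys: factor A, factor B, "A x B" label
    grand_mean: float
    cell_means: np.ndarray  # shape (2, 2)


def rm_anova_2x2(
    cells: np.ndarray, factor_names: tuple[str, str] = ("A", "B")
) -> AnovaResult:
    """2x2 fully within-subject ANOVA.

    Parameters
    ----------
    cells
        Array of shape ``(n_subjects, 2, 2)``: axis 1 indexes factor A's
        levels, axis 2 factor B's.
    factor_names
        Labels for the two factors; the interaction is keyed
        ``"<A> x <B>"``.

    Each effect is tested against its own subject-by-effect interaction
    (the standard univariate within-subject decomposition; with two-level
    factors sphericity holds trivially and ``df_den = n - 1``).  Effect sizes
    are partial eta squared, ``SS_effect / (SS_effect + SS_error)``.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3 or cells.shape[1:] != (2, 2):
        raise ValueError("cells must have shape (n_subjects, 2, 2)")
    if np.isnan(cells).any():
        raise ValueError("incomplete cells")
    n = cells.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    grand = cells.mean()
    subj = cells.mean(axis=(1, 2))  # (n,)
    mean_a = cells.mean(axis=(0, 2))  # (2,)
    mean_b = cells.mean(axis=(0, 1))  # (2,)
    mean_ab = cells.mean(axis=0)  # (2, 2)
    mean_sa = cells.mean(axis=2)  # (n, 2)
    mean_sb = cells.mean(axis=1)  # (n, 2)

    ss_a = 2 * n * ((mean_a - grand) ** 2).sum()
    ss_b = 2 * n * ((mean_b - grand) ** 2).sum()
    ss_ab = n * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_sa = 2 * ((mean_sa - subj[:, None] - mean_a[None, :] + grand) ** 2).sum()
    ss_sb = 2 * ((mean_sb - subj[:, None] - mean_b[None, :] + grand) ** 2).sum()
    expected = (
        subj[:, None, None]
        + mean_ab[None, :, :]
        + (mean_sa - subj[:, None])[:, :, None]
        + (mean_sb - subj[:, None])[:, None, :]
        - mean_a[None, :, None]
        - mean_b[None, None, :]
        + grand
    )
    ss_sab = ((cells - expected) ** 2).sum()

    df_den = n - 1
    effects = {}
    labels = (factor_names[0], factor_names[1], f"{factor_names[0]} x {factor_names[1]}")
    for label, ss_eff, ss_err in zip(
        labels, (ss_a, ss_b, ss_ab), (ss_sa, ss_sb, ss_sab)
    ):
        if ss_err == 0:
            if ss_eff == 0:
                F = 0.0
                p = 1.0
            else:
                raise DegenerateSampleError(f"zero error variance for effect {label}")
        else:
            F = (ss_eff / 1.0) / (ss_err / df_den)
            p = float(sps.f.sf(F, 1, df_den))
        denom = ss_eff + ss_err
        effects[label] = AnovaEffect(
            F=float(F),
            df_num=1,
            df_den=df_den,
            p=p,
            partial_eta_sq=float(ss_eff / denom) if denom > 0 else 0.0,
            ss_effect=float(ss_eff),
            ss_error=float(ss_err),
        )
    return AnovaResult(effects=effects, grand_mean=float(grand), cell_means=mean_ab)


# ---------------------------------------------------------------------------
# Power / sample size
# ---------------------------------------------------------------------------


def paired_t_power(n: int, dz: float, alpha: float = 0.05) -> float:
    """Power of the two-sided paired t-test at sample size ``n``.

    Exact noncentral-t evaluation with noncentrality ``dz*sqrt(n)`` and
    ``n - 1`` degrees of freedom.
    """
    if n < 2:
        return 0.0
    df = n - 1
    nc = dz * np.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


@dataclass(frozen=True)
class PowerSpec:
    dz: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.dz <= 0:
            raise ValueError("dz must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.target_power < 1):
            raise ValueError("target_power must lie in (0, 1)")


def required_sample_size(spec: PowerSpec, max_n: int = 100_000) -> int:
    """Smallest n whose two-sided paired t-test reaches the target power."""
    for n in range(2, max_n + 1):
        if paired_t_power(n, spec.dz, spec.alpha) >= spec.target_power:
            return n
    raise ValueError(f"required sample size exceeds max_n={max_n}")


# ---------------------------------------------------------------------------
# Descriptive confidence summary
# ---------------------------------------------------------------------------


def confidence_summary(logs: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate confidence by task, direction, and accuracy.

    ``logs`` needs columns task, direction, correct, confidence (integer
    levels, 1-based).  Returns, per cell: trial count, mean confidence level,
    and the proportion of trials at the top observed level ("confident" on the
    binary scale).  Purely descriptive; row order of the input is irrelevant.
    """
    required = {"task", "direction", "correct", "confidence"}
    missing = required - set(logs.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    top = logs["confidence"].max()
    out = (
        logs.groupby(["task", "direction", "correct"], sort=True)["confidence"]
        .agg(
            n_trials="size",
            mean_confidence="mean",
            prop_top_level=lambda s: float((s == top).mean()),
        )
        .reset_index()
    )
    return out
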