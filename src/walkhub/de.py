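"""Per-timepoint differential screening of case vs control expression.

The screen follows the usual two-stage rule for injury-model microarray
data: a gene is called differentially expressed at a timepoint when its
log2 fold change exceeds 0.585 in magnitude (a 1.5-fold change) *and* its
Benjamini-Hochberg adjusted p-value falls below 0.05.  Both inequalities
are strict.  The per-gene test is an ordinary pooled-variance two-sample
t-test; a moderated statistic can be plugged in through ``stat_fn``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma, psi
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: log2(1.5): the conventional 1.5-fold-change screening threshold.
DEFAULT_LFC_THRESHOLD = 0.585
DEFAULT_FDR_THRESHOLD = 0.05


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ExpressionExperiment:
    """A genes x samples matrix of log2 intensities plus sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample, log2 scale.
    samples
        DataFrame indexed by sample id with columns ``group`` and
        ``timepoint``; its index must match ``values.columns`` exactly.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        missing = {"group", "timepoint"} - set(self.samples.columns)
        if missing:
            raise ValidationError(f"sample sheet lacks columns: {sorted(missing)}")
        if set(self.values.columns) != set(self.samples.index):
            raise ValidationError("expression columns and sample sheet ids differ")
        # keep sample-sheet order authoritative
        self.values = self.values.loc[:, self.samples.index]
        cell_sizes = self.samples.groupby(["group", "timepoint"], observed=True).size()
        if (cell_sizes < 2).any():
            bad = cell_sizes[cell_sizes < 2].index.tolist()
            raise ValidationError(
                f"need >=2 samples per (group, timepoint) cell; too few in {bad}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def timepoints(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.samples["timepoint"]:
            seen.setdefault(t, None)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.samples["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def group_matrix(self, timepoint: str, group: str) -> np.ndarray:
        """Values (genes x replicates) for one (group, timepoint) cell."""
        mask = (self.samples["timepoint"] == timepoint) & (
            self.samples["group"] == group
        )
        cols = self.samples.index[mask]
        if len(cols) == 0:
            raise ValidationError(
                f"no samples for group {group!r} at timepoint {timepoint!r}"
            )
        return self.values.loc[:, cols].to_numpy(dtype=float)


def _case_control(
    experiment: ExpressionExperiment,
    timepoint: str,
    case_group: str,
    control_group: str,
) -> tuple[np.ndarray, np.ndarray]:
    if timepoint not in set(experiment.samples["timepoint"]):
        raise ValidationError(f"timepoint {timepoint!r} absent from experiment")
    return (
        experiment.group_matrix(timepoint, case_group),
        experiment.group_matrix(timepoint, control_group),
    )


def log_fold_change(
    experiment: ExpressionExperiment,
    timepoint: str,
    case_group: str = "SNI",
    control_group: str = "Sham",
) -> pd.Series:
    """Per-gene log2 fold change: mean(case) - mean(control) at a timepoint.

    Input values are already log2, so a difference of means is a log2
    fold change.  Sign convention: positive means up in the case group.
    """
    case, ctrl = _case_control(experiment, timepoint, case_group, control_group)
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    return pd.Series(lfc, index=experiment.gene_ids, name="logFC")


def two_sample_test(
    experiment: ExpressionExperiment,
    timepoint: str,
    case_group: str = "SNI",
    control_group: str = "Sham",
) -> pd.Series:
    """Two-sided pooled-variance t-test p-value per gene.

    Degenerate genes with zero pooled variance get p=1 when the group
    means coincide and the smallest positive float otherwise; both cases
    are logged.
    """
    case, ctrl = _case_control(experiment, timepoint, case_group, control_group)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >=2 samples per group for a variance estimate")
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0.0
    if degenerate.any():
        p = np.where(degenerate, np.where(diff == 0.0, 1.0, np.finfo(float).tiny), p)
        logger.warning(
            "%d gene(s) with zero pooled variance at %s; p forced to 1 or tiny",
            int(degenerate.sum()),
            timepoint,
        )
    return pd.Series(p, index=experiment.gene_ids, name="p_value")


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # good starting point: trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(50):
        tri = polygamma(1, x)
        step = tri * (tri - y) / polygamma(2, x)
        x = x - step
        if np.all(np.abs(step) < 1e-10 * x):
            break
    return x


def moderated_t_test(
    experiment: ExpressionExperiment,
    timepoint: str,
    case_group: str = "SNI",
    control_group: str = "Sham",
) -> pd.Series:
    """Empirical-Bayes moderated two-sample t-test p-value per gene.

    Gene-wise sample variances are modelled as scaled inverse-chi-square
    draws around a common prior variance s0^2 with d0 prior degrees of
    freedom; (d0, s0^2) are estimated from the observed log-variance
    distribution by moment matching, each posterior variance is the
    precision-weighted blend (d0*s0^2 + d*s^2)/(d0 + d), and the t
    statistic is referred to a t distribution with d0 + d degrees of
    freedom.  With few replicates this borrows variance information
    across genes and restores the power that a 4-df ordinary t lacks.
    """
    case, ctrl = _case_control(experiment, timepoint, case_group, control_group)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >=2 samples per group for a variance estimate")
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    d = n1 + n2 - 2
    sp2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / d
    positive = sp2 > 0
    if not positive.any():
        raise ValidationError("all genes have zero variance; cannot moderate")
    # moment-match log(s^2) = log(s0^2) + log(chi2_d/d) - log(chi2_d0/d0)
    z = np.log(sp2[positive])
    e = z - psi(d / 2.0) + np.log(d / 2.0)
    excess = np.var(e, ddof=1) - polygamma(1, d / 2.0)
    if excess > 1e-8:
        d0 = float(2.0 * _trigamma_inverse(np.array([excess]))[0])
        s0_sq = float(np.exp(np.mean(e) - psi(d0 / 2.0) + np.log(d0 / 2.0)))
        post_var = (d0 * s0_sq + d * sp2) / (d0 + d)
        df_total = d0 + d
    else:
        # no detectable gene-to-gene variance heterogeneity: complete shrinkage
        s0_sq = float(np.exp(np.mean(e)))
        post_var = np.full_like(sp2, s0_sq)
        df_total = np.inf
    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    degenerate = se == 0.0
    if degenerate.any():
        p = np.where(degenerate, np.where(diff == 0.0, 1.0, np.finfo(float).tiny), p)
        logger.warning(
            "%d gene(s) with zero posterior variance at %s", int(degenerate.sum()), timepoint
        )
    return pd.Series(p, index=experiment.gene_ids, name="p_value")


def bh_adjust(p_values: Sequence[float] | pd.Series) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    fdr = multipletests(p, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(fdr, index=p_values.index, name="fdr")
    return fdr


def de_table(
    experiment: ExpressionExperiment,
    timepoint: str,
    case_group: str = "SNI",
    control_group: str = "Sham",
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    stat_fn: Callable[..., pd.Series] | None = None,
) -> pd.DataFrame:
    """Full differential table for one timepoint.

    Columns: ``logFC``, ``p_value``, ``fdr``, ``passes``.  ``stat_fn`` is a
    hook for alternative test statistics (e.g. a moderated t); it must have
    the signature of :func:`two_sample_test`.
    """
    if lfc_threshold <= 0 or fdr_threshold <= 0:
        raise ValidationError("screening thresholds must be positive")
    test = stat_fn or two_sample_test
    lfc = log_fold_change(experiment, timepoint, case_group, control_group)
    p = test(experiment, timepoint, case_group, control_group)
    fdr = bh_adjust(p)
    passes = (lfc.abs() > lfc_threshold) & (fdr < fdr_threshold)
    return pd.DataFrame(
        {"logFC": lfc, "p_value": p, "fdr": fdr, "passes": passes}
    )


def screen_degs(
    table: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> set[str]:
    """Genes with |logFC| strictly above and FDR strictly below threshold."""
    if lfc_threshold <= 0 or fdr_threshold <= 0:
        raise ValidationError("screening thresholds must be positive")
    mask = (table["logFC"].abs() > lfc_threshold) & (table["fdr"] < fdr_threshold)
    return set(table.index[mask])
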