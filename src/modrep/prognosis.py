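"""Selection of prognostic gene modules.

For every gene set, the per-sample KS enrichment scores are compared between
good-outcome and bad-outcome patients with the unequal-variance (Welch)
two-sample t statistic

    t = (x̄ − ȳ) / sqrt(s_x²/n + s_y²/m)

where x are the good-outcome scores (n samples), y the bad-outcome scores
(m samples) and s² the unbiased sample variances.  Two-sided p-values use
Welch–Satterthwaite degrees of freedom.  A module is *prognostic* when its
p-value beats the threshold in every cohort (the multi-cohort intersection
rule); no multiple-testing correction is applied by default, an optional
Benjamini–Hochberg mode changes the per-cohort criterion to FDR < alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import EnrichmentMatrix
from .io import OUTCOME_BAD, OUTCOME_GOOD

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class ModuleSelection:
    """Per-cohort p-values and the intersection-selected module list."""

    per_cohort_p: pd.DataFrame  # sets x cohorts
    selected: list[str]
    alpha: float
    bh: bool = False
    per_cohort_t: pd.DataFrame | None = field(default=None, repr=False)

    def to_tsv(self, path, header_lines=None) -> None:
        df = self.per_cohort_p.copy()
        df["selected"] = [int(s in set(self.selected)) for s in df.index]
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index_label="gene_set", lineterminator="\n")


def _split_groups(scores: np.ndarray, outcome: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = outcome.to_numpy()
    good = scores[..., labels == OUTCOME_GOOD]
    bad = scores[..., labels == OUTCOME_BAD]
    return good, bad


def module_t_test(scores: pd.Series, outcome: pd.Series) -> tuple[float, float]:
    """Welch t statistic and two-sided p for one module's scores.

    ``scores`` and ``outcome`` are aligned per-sample; good-outcome samples
    form group x, bad-outcome samples group y, so positive t means higher
    enrichment in good-prognosis patients.
    """
    scores = scores.reindex(outcome.index)
    vals = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite enrichment score")
    x, y = _split_groups(vals, outcome)
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise ValueError(f"each outcome group needs >= 2 samples (got {n} good, {m} bad)")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / n + vy / m
    diff = x.mean() - y.mean()
    if se2 == 0.0:
        if diff == 0.0:
            raise ValueError("zero pooled variance: both groups constant and equal")
        return (float(np.inf) if diff > 0 else float(-np.inf)), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((vx / n) ** 2 / (n - 1) + (vy / m) ** 2 / (m - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def _welch_rows(matrix: np.ndarray, outcome: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch test over the rows of a sets x samples matrix."""
    x, y = _split_groups(matrix, outcome)
    res = stats.ttest_ind(x, y, axis=-1, equal_var=False)
    return np.asarray(res.statistic, dtype=float), np.asarray(res.pvalue, dtype=float)


def select_modules(
    cohorts: dict[str, tuple[EnrichmentMatrix, pd.Series]],
    alpha: float = DEFAULT_ALPHA,
    bh: bool = False,
) -> ModuleSelection:
    """Select modules significant in *every* cohort.

    Parameters
    ----------
    cohorts : dict
        cohort id -> (enrichment matrix, per-sample outcome labels).
    alpha : float
        Per-cohort significance threshold on the (raw or BH-adjusted)
        two-sided p-value.
    bh : bool
        If True, apply per-cohort Benjamini–Hochberg correction before
        thresholding.

    The selected list is ordered by ascending maximum p across cohorts
    (ties by set name) so downstream reports are deterministic.
    """
    if not cohorts:
        raise ValueError("at least one cohort required")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")

    cohort_ids = list(cohorts)
    first = cohorts[cohort_ids[0]][0]
    common = [
        s
        for s in first.set_names
        if all(s in set(cohorts[c][0].set_names) for c in cohort_ids[1:])
    ]
    if not common:
        raise ValueError("no gene set scored in all cohorts")

    pvals = pd.DataFrame(index=common, columns=cohort_ids, dtype=float)
    tvals = pd.DataFrame(index=common, columns=cohort_ids, dtype=float)
    crit = pd.DataFrame(index=common, columns=cohort_ids, dtype=float)
    for cid in cohort_ids:
        em, outcome = cohorts[cid]
        outcome = outcome.reindex(em.samples)
        mat = em.scores.loc[common].to_numpy(dtype=float)
        t, p = _welch_rows(mat, outcome)
        pvals[cid] = p
        tvals[cid] = t
        if bh:
            crit[cid] = multipletests(p, method="fdr_bh")[1]
        else:
            crit[cid] = p

    ok = (crit < alpha).all(axis=1) & crit.notna().all(axis=1)
    hits = crit.loc[ok]
    order = sorted(hits.index, key=lambda s: (hits.loc[s].max(), s))
    logger.info(
        "select_modules: %d/%d modules significant in all %d cohorts (alpha=%g%s)",
        len(order), len(common), len(cohort_ids), alpha, ", BH" if bh else "",
    )
    return ModuleSelection(
        per_cohort_p=pvals, selected=order, alpha=alpha, bh=bh, per_cohort_t=tvals
    )
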