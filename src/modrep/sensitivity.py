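"""Drug-sensitivity gene modules from a GI50 screen.

A drug's activity profile is its vector of −log10 GI50 values across the
screen's cell-line panel.  Each gene's baseline expression across the same
panel is correlated (Pearson) with that profile; genes whose two-sided
p-value beats the threshold form the drug's *sensitivity module*.  The
p-value comes from the t transform t = r·sqrt((n−2)/(1−r²)) on n−2 degrees
of freedom, over pairwise-complete cell lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DrugActivityRecord, ExpressionCohort, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_PAIRS = 30
DEFAULT_COVERAGE_FRAC = 0.8


@dataclass
class ActivityMatrix:
    """Aggregated drugs x cell-lines −log10 GI50 activity (NaN = unmeasured)."""

    values: pd.DataFrame  # drugs (NSC) x cell lines
    names: dict[str, str] = field(default_factory=dict)  # NSC -> compound name

    @property
    def drugs(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.columns)

    def to_records(self) -> list[DrugActivityRecord]:
        """Re-emit as one record per measured (drug, cell line) pair."""
        out = []
        for nsc, row in self.values.iterrows():
            for cell, v in row.items():
                if np.isfinite(v):
                    out.append(
                        DrugActivityRecord(
                            nsc=str(nsc), cell=str(cell), nloggi50=float(v),
                            compound=self.names.get(str(nsc), ""),
                        )
                    )
        return out


@dataclass
class SensitivityModule:
    """Genes whose baseline expression tracks one drug's activity profile."""

    drug: str
    compound: str
    genes: tuple[str, ...]
    stats: pd.DataFrame  # member genes x (r, p, n)

    def __len__(self) -> int:
        return len(self.genes)


def normalize_cell_name(name: str) -> str:
    return name.strip().upper()


def aggregate_activity(
    records: list[DrugActivityRecord],
    coverage_frac: float = DEFAULT_COVERAGE_FRAC,
) -> ActivityMatrix:
    """Aggregate screen records into a drugs x cell-lines matrix.

    Replicate measurements of the same (drug, cell line) pair — e.g. runs at
    different highest-tested concentrations — are averaged.  Drugs measured
    in fewer than ``coverage_frac`` of the panel's cell lines are dropped
    (the screen-matching step that reduces the usable compound list).
    """
    if not records:
        raise ValueError("empty drug-record list")
    df = pd.DataFrame(
        {
            "nsc": [r.nsc for r in records],
            "cell": [normalize_cell_name(r.cell) for r in records],
            "nloggi50": [r.nloggi50 for r in records],
        }
    )
    mat = df.groupby(["nsc", "cell"], sort=False)["nloggi50"].mean().unstack("cell")
    panel_size = mat.shape[1]
    coverage = mat.notna().sum(axis=1) / panel_size
    keep = coverage >= coverage_frac
    if (~keep).any():
        logger.info(
            "aggregate_activity: dropped %d/%d drugs below %.0f%% panel coverage",
            int((~keep).sum()), len(mat), 100 * coverage_frac,
        )
    mat = mat.loc[keep]
    names = {}
    for r in records:
        if r.compound and r.nsc not in names:
            names[r.nsc] = r.compound
    return ActivityMatrix(values=mat, names=names)


def gene_drug_correlation(
    expression: pd.Series,
    activity: pd.Series,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> tuple[float, float, int] | None:
    """Pearson r, two-sided p and pair count over pairwise-complete cells.

    Returns ``None`` when fewer than ``min_pairs`` complete pairs exist or
    either vector has zero variance over the complete pairs (the gene is
    skipped, not an error).
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(activity.reindex(expression.index) if isinstance(activity, pd.Series) else activity, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_pairs:
        return None
    x, y = x[mask], y[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    p = _pearson_p(r, n)
    return r, p, n


def _pearson_p(r, n):
    """Two-sided p from the t transform of a Pearson correlation."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), n - 2), 0.0)
    return np.minimum(p, 1.0) if np.ndim(p) else float(min(p, 1.0))


def build_sensitivity_modules(
    expr: ExpressionCohort,
    acts: ActivityMatrix,
    alpha: float = DEFAULT_ALPHA,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> list[SensitivityModule]:
    """One sensitivity module per drug: all genes correlated with the drug's
    activity at p < alpha (both signs admitted).

    Cell lines are matched by exact name after upper-casing and whitespace
    stripping; unmatched lines are logged and dropped.  Empty modules are
    permitted (and logged).
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    expr_cells = {normalize_cell_name(c): c for c in expr.samples}
    act_cells = {normalize_cell_name(c): c for c in acts.cell_lines}
    common = [c for c in act_cells if c in expr_cells]
    if not common:
        raise ValueError("no cell lines in common between expression and activity")
    unmatched = sorted(set(expr_cells) ^ set(act_cells))
    if unmatched:
        logger.info("build_sensitivity_modules: %d unmatched cell-line names: %s",
                    len(unmatched), unmatched[:10])

    X = expr.values[[expr_cells[c] for c in common]].to_numpy(dtype=float)  # genes x lines
    genes = np.asarray(expr.values.index)
    modules: list[SensitivityModule] = []
    for nsc in acts.drugs:
        y = acts.values.loc[nsc, [act_cells[c] for c in common]].to_numpy(dtype=float)
        mask = np.isfinite(y)
        fin_x = np.isfinite(X)
        pair = fin_x & mask[None, :]
        n_g = pair.sum(axis=1)

        Xm = np.where(pair, X, 0.0)
        Ym = np.where(pair, y[None, :], 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            mx = Xm.sum(axis=1) / n_g
            my = Ym.sum(axis=1) / n_g
            dx = np.where(pair, X - mx[:, None], 0.0)
            dy = np.where(pair, y[None, :] - my[:, None], 0.0)
            sxx = (dx**2).sum(axis=1)
            syy = (dy**2).sum(axis=1)
            r = (dx * dy).sum(axis=1) / np.sqrt(sxx * syy)

        usable = (n_g >= min_pairs) & (sxx > 0) & (syy > 0)
        n_skipped = int((~usable).sum())
        r = np.where(usable, r, np.nan)
        p = np.full_like(r, np.nan)
        if usable.any():
            p[usable] = _pearson_p(r[usable], n_g[usable])
        member = usable & (p < alpha)
        stats_df = pd.DataFrame(
            {"r": r[member], "p": p[member], "n": n_g[member]},
            index=genes[member],
        )
        module = SensitivityModule(
            drug=str(nsc),
            compound=acts.names.get(str(nsc), ""),
            genes=tuple(genes[member]),
            stats=stats_df,
        )
        if n_skipped:
            logger.debug("drug %s: skipped %d genes (few pairs or zero variance)",
                         nsc, n_skipped)
        if not module.genes:
            logger.info("drug %s: empty sensitivity module", nsc)
        modules.append(module)
    return modules


def modules_to_collection(modules: list[SensitivityModule]) -> GeneSetCollection:
    """Persistable GMT view of the modules (set name = 'NSC<id>|<compound>')."""
    coll = GeneSetCollection(source="sensitivity modules")
    for m in modules:
        if not m.genes:
            continue
        coll.add(GeneSet(name=f"NSC{m.drug}|{m.compound}", category="custom",
                         members=m.genes))
    return coll


def write_module_stats(modules: list[SensitivityModule], path, header_lines=None) -> None:
    """Companion TSV of per-gene correlation statistics for every module."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("nsc\tcompound\tgene\tr\tp\tn\n")
        for m in modules:
            for gene, row in m.stats.iterrows():
                fh.write(
                    f"{m.drug}\t{m.compound}\t{gene}\t{row['r']!r}\t{row['p']!r}\t{int(row['n'])}\n"
                )
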