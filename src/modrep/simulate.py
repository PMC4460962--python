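"""Synthetic inputs with planted ground truth.

The generator emulates the four inputs of the pipeline: patient expression
cohorts with binary prognosis labels, a gene-set collection, a cell-line
baseline expression panel, and a DTP-style drug screen table.

Model
-----
Baseline expression is standard normal per gene and sample.  A subset of
``n_planted`` gene sets is *planted*: each draws its members from a shared
"disease program" pool of ``pool_size`` genes, so planted sets overlap one
another heavily — the way prognostic modules do in real annotation
collections, where the significant terms are near-duplicate descriptions of
one proliferation program.  Pool genes carry a shared per-sample latent
factor with loading ``coexpression`` (mutually correlated, as co-regulated
genes are in tumours and cell lines, while every gene stays marginally
N(0, 1)).  In bad-outcome patients the pool genes are additionally shifted
by ``+delta``.  Decoy sets draw their members from the non-pool genes so
they are genuinely null with respect to outcome; keeping the pool small
(default twice the set size) also keeps the rank displacement that a large
shifted gene block would impose on every other gene — and hence on decoy
sets' KS scores — negligible.

In the drug screen, each *effective* drug's activity per cell line is
``rho * z + sqrt(1 - rho^2) * noise`` where ``z`` is the standardised mean
baseline expression of one planted set's genes in that cell line; decoy
drugs are pure noise.  Replicate screen rows at two highest-tested
concentrations are planted for a random fraction of (drug, cell line) pairs
to exercise the aggregation rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio

DEFAULT_COEXPRESSION = 0.7


@dataclass
class GroundTruth:
    """What was planted, and every parameter needed to regenerate it."""

    prognostic_sets: tuple[str, ...] = ()
    effective_drugs: tuple[str, ...] = ()
    tracked_sets: dict[str, str] = field(default_factory=dict)  # drug -> set
    params: dict[str, object] = field(default_factory=dict)


def _gene_names(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def _cell_names(n: int) -> list[str]:
    return [f"CL{i:03d}" for i in range(1, n + 1)]


def gen_cohorts(
    n_genes: int = 2000,
    n_sets: int = 200,
    set_size: int = 20,
    n_planted: int = 20,
    n_good: int = 60,
    n_bad: int = 60,
    delta: float = 1.5,
    n_cohorts: int = 3,
    coexpression: float = DEFAULT_COEXPRESSION,
    pool_size: int | None = None,
    seed: int = 0,
) -> tuple[list[mio.ExpressionCohort], mio.GeneSetCollection, GroundTruth]:
    """Generate labelled patient cohorts plus the gene-set collection.

    Planted sets draw ``set_size`` members each from a shared disease-program
    pool of ``pool_size`` genes (default ``2 * set_size``), whose expression
    is shifted by ``+delta`` in bad-outcome samples of *every* cohort; all
    cohorts share the gene universe.  Deterministic given ``seed``.
    """
    if pool_size is None:
        pool_size = 2 * set_size if n_planted > 0 else 0
    if n_planted > n_sets:
        raise ValueError(f"n_planted ({n_planted}) exceeds n_sets ({n_sets})")
    if n_planted > 0 and not set_size <= pool_size <= n_genes:
        raise ValueError(
            f"pool_size must lie in [set_size, n_genes], got {pool_size}"
        )
    if n_sets > n_planted and n_genes - pool_size < set_size:
        raise ValueError("not enough non-pool genes for decoy sets")
    if n_good < 2 or n_bad < 2:
        raise ValueError("each outcome group needs >= 2 samples")
    if not 0 <= coexpression < 1:
        raise ValueError("coexpression loading must be in [0, 1)")

    rng = np.random.default_rng(seed)
    genes = np.asarray(_gene_names(n_genes))

    pool_idx = rng.choice(n_genes, size=pool_size, replace=False)
    other_idx = np.setdiff1d(np.arange(n_genes), pool_idx)
    planted_set_pos = set(rng.choice(n_sets, size=n_planted, replace=False).tolist())

    collection = mio.GeneSetCollection(source=f"synthetic(seed={seed})")
    planted_names: list[str] = []
    planted_member_idx: set[int] = set()
    for i in range(n_sets):
        name = f"M{i:04d}"
        category = "BP" if i % 2 == 0 else "CC"
        if i in planted_set_pos:
            idx = rng.choice(pool_idx, size=set_size, replace=False)
            planted_member_idx.update(idx.tolist())
            planted_names.append(name)
        else:
            idx = rng.choice(other_idx, size=set_size, replace=False)
        collection.add(
            mio.GeneSet(name=name, category=category,
                        members=tuple(sorted(genes[idx])))
        )

    n_samples = n_good + n_bad
    w = coexpression
    planted_mask = np.zeros(n_genes, dtype=bool)
    planted_mask[sorted(planted_member_idx)] = True
    cohorts: list[mio.ExpressionCohort] = []
    for k in range(n_cohorts):
        cid = f"cohort{k + 1}"
        vals = rng.standard_normal((n_genes, n_samples))
        if planted_mask.any() and w > 0:
            f = rng.standard_normal(n_samples)
            vals[planted_mask] = (
                w * f[None, :] + np.sqrt(1.0 - w**2) * vals[planted_mask]
            )
        vals[np.ix_(planted_mask, np.arange(n_good, n_samples))] += delta
        samples = [f"{cid}_S{j:03d}" for j in range(1, n_samples + 1)]
        outcome = pd.Series(
            [mio.OUTCOME_GOOD] * n_good + [mio.OUTCOME_BAD] * n_bad, index=samples
        )
        cohorts.append(
            mio.ExpressionCohort(
                cohort_id=cid,
                values=pd.DataFrame(vals, index=genes, columns=samples),
                outcome=outcome,
            )
        )

    truth = GroundTruth(
        prognostic_sets=tuple(planted_names),
        params={
            "n_genes": n_genes, "n_sets": n_sets, "set_size": set_size,
            "n_planted": n_planted, "n_good": n_good, "n_bad": n_bad,
            "delta": delta, "n_cohorts": n_cohorts,
            "coexpression": coexpression, "pool_size": pool_size,
            "cohort_seed": seed,
        },
    )
    return cohorts, collection, truth


def gen_drug_screen(
    n_cell_lines: int = 60,
    n_drugs: int = 20,
    n_effective: int = 1,
    rho: float = 0.7,
    collection: mio.GeneSetCollection | None = None,
    truth: GroundTruth | None = None,
    seed: int = 0,
    replicate_frac: float = 0.1,
) -> tuple[mio.ExpressionCohort, list[mio.DrugActivityRecord], GroundTruth]:
    """Generate the cell-line baseline profile and the drug screen table.

    Effective drugs' activity tracks the standardised mean expression of one
    planted set's genes at correlation ``rho``; activity is emitted as
    −log10 GI50 around 6.  Deterministic given ``seed``.
    """
    if truth is None or collection is None:
        raise ValueError("gen_drug_screen needs the collection and truth from gen_cohorts")
    if n_effective > n_drugs:
        raise ValueError(f"n_effective ({n_effective}) exceeds n_drugs ({n_drugs})")
    if n_effective > 0 and not truth.prognostic_sets:
        raise ValueError("no planted prognostic sets to track")
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n_genes = int(truth.params["n_genes"])
    w = float(truth.params.get("coexpression", 0.0))
    genes = np.asarray(_gene_names(n_genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    planted_mask = np.zeros(n_genes, dtype=bool)
    for name in truth.prognostic_sets:
        planted_mask[[gene_pos[g] for g in collection[name].members]] = True

    cells = _cell_names(n_cell_lines)
    vals = rng.standard_normal((n_genes, n_cell_lines))
    if planted_mask.any() and w > 0:
        f = rng.standard_normal(n_cell_lines)
        vals[planted_mask] = w * f[None, :] + np.sqrt(1.0 - w**2) * vals[planted_mask]
    cell_expr = mio.ExpressionCohort(
        cohort_id="cell_lines",
        values=pd.DataFrame(vals, index=genes, columns=cells),
    )

    effective_idx = set(rng.choice(n_drugs, size=n_effective, replace=False).tolist()) \
        if n_effective else set()
    panels = ["Breast", "Renal", "Colon", "Leukemia", "CNS", "Melanoma"]
    records: list[mio.DrugActivityRecord] = []
    effective_drugs: list[str] = []
    tracked: dict[str, str] = {}
    for d in range(n_drugs):
        nsc = str(1000 + d)
        if d in effective_idx:
            set_name = str(rng.choice(np.asarray(truth.prognostic_sets)))
            idx = [gene_pos[g] for g in collection[set_name].members]
            driver = vals[idx, :].mean(axis=0)
            driver = (driver - driver.mean()) / driver.std()
            activity = rho * driver + np.sqrt(1.0 - rho**2) * rng.standard_normal(n_cell_lines)
            effective_drugs.append(nsc)
            tracked[nsc] = set_name
        else:
            activity = rng.standard_normal(n_cell_lines)
        nloggi50 = 6.0 + activity
        replicate = rng.random(n_cell_lines) < replicate_frac
        for li, cell in enumerate(cells):
            common = dict(
                nsc=nsc, cell=cell, panel=panels[li % len(panels)],
                compound=f"compound-{nsc}", cas="0000-00-0",
            )
            if replicate[li]:
                records.append(mio.DrugActivityRecord(
                    nloggi50=float(nloggi50[li] + 0.05), lconc=-4.0, **common))
                records.append(mio.DrugActivityRecord(
                    nloggi50=float(nloggi50[li] - 0.05), lconc=-5.0, **common))
            else:
                records.append(mio.DrugActivityRecord(
                    nloggi50=float(nloggi50[li]), lconc=-4.0, **common))

    new_truth = replace(
        truth,
        effective_drugs=tuple(effective_drugs),
        tracked_sets={**truth.tracked_sets, **tracked},
        params={
            **truth.params,
            "n_cell_lines": n_cell_lines, "n_drugs": n_drugs,
            "n_effective": n_effective, "rho": rho,
            "replicate_frac": replicate_frac, "screen_seed": seed,
        },
    )
    return cell_expr, records, new_truth


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_truth(truth: GroundTruth, path) -> None:
    """Flat key=value manifest; sufficient to regenerate everything."""
    with open(path, "w") as fh:
        fh.write("prognostic_sets=" + ",".join(truth.prognostic_sets) + "\n")
        fh.write("effective_drugs=" + ",".join(truth.effective_drugs) + "\n")
        fh.write(
            "tracked_sets="
            + ",".join(f"{k}:{v}" for k, v in truth.tracked_sets.items())
            + "\n"
        )
        for key in sorted(truth.params):
            fh.write(f"param.{key}={truth.params[key]!r}\n")


def read_truth(path) -> GroundTruth:
    fields: dict[str, str] = {}
    params: dict[str, object] = {}
    with open(path) as fh:
        for line in fh:
            key, _, value = line.rstrip("\n").partition("=")
            if key.startswith("param."):
                import ast

                params[key[6:]] = ast.literal_eval(value)
            else:
                fields[key] = value
    tracked = {}
    if fields.get("tracked_sets"):
        tracked = dict(kv.split(":") for kv in fields["tracked_sets"].split(","))
    return GroundTruth(
        prognostic_sets=tuple(s for s in fields.get("prognostic_sets", "").split(",") if s),
        effective_drugs=tuple(s for s in fields.get("effective_drugs", "").split(",") if s),
        tracked_sets=tracked,
        params=params,
    )


def write_inputs(
    outdir,
    cohorts: list[mio.ExpressionCohort],
    collection: mio.GeneSetCollection,
    cell_expr: mio.ExpressionCohort,
    records: list[mio.DrugActivityRecord],
    truth: GroundTruth,
) -> dict[str, Path]:
    """Emit every pipeline input in its exchange format; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cohort in cohorts:
        e = outdir / f"expression_{cohort.cohort_id}.tsv"
        o = outdir / f"outcome_{cohort.cohort_id}.tsv"
        mio.write_expression(cohort, e)
        mio.write_outcome(cohort.outcome, o)
        paths[f"expression_{cohort.cohort_id}"] = e
        paths[f"outcome_{cohort.cohort_id}"] = o
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    mio.write_gmt(collection, paths["gene_sets"])
    paths["cell_expression"] = outdir / "cell_line_expression.tsv"
    mio.write_expression(cell_expr, paths["cell_expression"])
    paths["drug_screen"] = outdir / "drug_screen.tsv"
    mio.write_drug_table(records, paths["drug_screen"])
    paths["ground_truth"] = outdir / "ground_truth.txt"
    write_truth(truth, paths["ground_truth"])
    return paths
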