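"""Drug–disease linkage by hypergeometric gene-set overlap.

A drug is linked to a prognostic gene module when the overlap between the
module and the drug's sensitivity module is larger than chance.  With a
universe of M genes, a prognostic module of N genes, a sensitivity module of
m genes and an observed overlap of n genes, the upper-tail p-value is

    P = Σ_{x ≥ n} C(N, x) · C(M−N, m−x) / C(M, m)

(the tail *includes* x = n).  Drugs are ranked by S_d, their number of
significantly linked prognostic modules; the Effect Score is S_d divided by
half the number of prognostic modules, so a drug linking every module scores
2 and a drug linking half of them scores 1.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sensitivity import SensitivityModule

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

_TINY = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class DrugDiseaseLink:
    """One candidate (drug, prognostic module) connection."""

    drug: str
    compound: str
    module: str
    overlap_n: int
    module_N: int
    sens_m: int
    universe_M: int
    p: float
    significant: bool


@dataclass
class DrugRanking:
    """Ranked drug table: S_d links per drug plus the Effect Score."""

    rows: pd.DataFrame  # rank, drug, compound, n_linked_modules, effect_score, best_p
    alpha: float
    n_prognostic_modules: int

    def to_tsv(self, path, header_lines=None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.rows.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def hypergeom_overlap(universe_M: int, module_N: int, sens_m: int, overlap_n: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= overlap_n), tail inclusive."""
    if universe_M <= 0:
        raise ValueError("universe size must be positive")
    if not (0 <= module_N <= universe_M and 0 <= sens_m <= universe_M):
        raise ValueError("set sizes must lie in [0, universe size]")
    if not 0 <= overlap_n <= min(module_N, sens_m):
        raise ValueError(
            f"overlap {overlap_n} outside [0, min({module_N}, {sens_m})]"
        )
    p = float(stats.hypergeom.sf(overlap_n - 1, universe_M, module_N, sens_m))
    return min(max(p, _TINY), 1.0)


def link_drugs(
    prog_modules: dict[str, tuple],
    sens_modules: list[SensitivityModule],
    universe,
    alpha: float = DEFAULT_ALPHA,
) -> list[DrugDiseaseLink]:
    """Candidate links for every (drug, prognostic module) pair.

    All gene sets are intersected with ``universe`` before counting.  Every
    candidate is returned; those with p < alpha carry ``significant=True``.
    """
    if not prog_modules:
        raise ValueError("empty prognostic module selection")
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    M = len(universe)
    prog = {name: set(genes) & universe for name, genes in prog_modules.items()}
    links: list[DrugDiseaseLink] = []
    for sm in sens_modules:
        sgenes = set(sm.genes) & universe
        for name, pgenes in prog.items():
            n = len(pgenes & sgenes)
            p = hypergeom_overlap(M, len(pgenes), len(sgenes), n)
            links.append(
                DrugDiseaseLink(
                    drug=sm.drug,
                    compound=sm.compound,
                    module=name,
                    overlap_n=n,
                    module_N=len(pgenes),
                    sens_m=len(sgenes),
                    universe_M=M,
                    p=p,
                    significant=p < alpha,
                )
            )
    return links


def rank_drugs(links: list[DrugDiseaseLink], n_prognostic_modules: int,
               alpha: float = DEFAULT_ALPHA) -> DrugRanking:
    """Rank drugs by number of significant links; attach the Effect Score.

    Effect Score = S_d / (P/2) with P prognostic modules; ties in S_d break
    by the drug's best (smallest) link p, then by drug identifier.
    """
    if n_prognostic_modules <= 0:
        raise ValueError("number of prognostic modules must be positive")
    if not links:
        raise ValueError("no links to rank")
    by_drug: dict[str, list[DrugDiseaseLink]] = {}
    for ln in links:
        by_drug.setdefault(ln.drug, []).append(ln)
    recs = []
    for drug, lns in by_drug.items():
        s_d = sum(ln.significant for ln in lns)
        best_p = min(ln.p for ln in lns)
        recs.append(
            {
                "drug": drug,
                "compound": lns[0].compound,
                "n_linked_modules": s_d,
                "effect_score": s_d / (n_prognostic_modules / 2.0),
                "best_p": best_p,
            }
        )
    recs.sort(key=lambda r: (-r["n_linked_modules"], r["best_p"], r["drug"]))
    df = pd.DataFrame(recs)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return DrugRanking(rows=df, alpha=alpha, n_prognostic_modules=n_prognostic_modules)


def rank_by_signature(
    signature,
    sens_modules: list[SensitivityModule],
    universe,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Gene-signature comparison mode: rank drugs by raw overlap with a
    fixed prognostic gene signature (overlap count descending), reporting
    the hypergeometric p alongside."""
    universe = set(universe)
    sig = set(signature) & universe
    if not sig:
        raise ValueError("empty signature after universe intersection")
    M, N = len(universe), len(sig)
    recs = []
    for sm in sens_modules:
        sgenes = set(sm.genes) & universe
        n = len(sig & sgenes)
        p = hypergeom_overlap(M, N, len(sgenes), n)
        recs.append(
            {"drug": sm.drug, "compound": sm.compound, "n_overlap": n, "p": p}
        )
    recs.sort(key=lambda r: (-r["n_overlap"], r["p"], r["drug"]))
    df = pd.DataFrame(recs)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def export_network(links: list[DrugDiseaseLink], path, header_lines=None) -> None:
    """Write the significant links as a typed bipartite TSV edge list.

    Columns: source (drug), target (module), source_type, target_type,
    overlap_n, p.  Field values containing tabs/quotes are quoted.
    """
    with open(path, "w", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n",
                            quoting=csv.QUOTE_MINIMAL)
        writer.writerow(["source", "target", "source_type", "target_type",
                         "overlap_n", "p"])
        for ln in links:
            if ln.significant:
                label = f"{ln.compound} (NSC {ln.drug})" if ln.compound else ln.drug
                writer.writerow([label, ln.module, "drug", "module",
                                 ln.overlap_n, repr(ln.p)])
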