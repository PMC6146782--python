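"""IBS distances, neighbor-joining trees, and genome-wide group FST.

Pairwise distance between individuals is 1 minus identity-by-state similarity,
where similarity at a co-called locus is the shared-allele fraction (identical
homozygotes 1, homozygote vs heterozygote 0.5, opposite homozygotes 0). Trees
are built with the Saitou-Nei neighbor-joining algorithm and serialised as
Newick. Genome-wide differentiation between groups is the unweighted mean of
per-locus FST over loci passing a call-rate filter, with a
leave-one-chromosome-out jackknife standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .freqio import BreedFrequencyTable
from .sweepscan import fst_locus


@dataclass
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def write_phylip(self, path) -> None:
        """Square PHYLIP distance-matrix format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for name, row in zip(self.taxa, self.d):
                fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def dosage_matrix(sites) -> tuple[np.ndarray, list[str]]:
    """(samples x loci) alt-dosage matrix from a stream of variant sites.

    NaN marks missing calls; hemizygous calls contribute their single allele
    (dosage 0 or 1).
    """
    cols = []
    names: list[str] | None = None
    for s in sites:
        names = list(s.samples)
        called = s.alleles >= 0
        dose = np.where(called, (s.alleles == 1), 0).sum(axis=1).astype(float)
        dose[~called.any(axis=1)] = np.nan
        cols.append(dose)
    if names is None:
        raise ValueError("no sites supplied")
    return np.array(cols).T, names


def ibs_distance(genotypes: np.ndarray, taxa: list[str]) -> DistanceMatrix:
    """1 - IBS similarity from a (samples x loci) alt-dosage matrix.

    Dosages are 0/1/2 with NaN for missing calls; each pair uses its
    pairwise-complete loci. A pair with no co-called locus raises.
    """
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples")
    d = np.zeros((n, n))
    called = ~np.isnan(g)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            if not both.any():
                raise ValueError(f"no co-called loci for pair ({taxa[i]}, {taxa[j]})")
            sim = 1.0 - np.abs(g[i, both] - g[j, both]) / 2.0
            d[i, j] = d[j, i] = 1.0 - float(sim.mean())
    return DistanceMatrix(taxa=tuple(taxa), d=d)


class _Node:
    __slots__ = ("name", "children")  # children: list of (node, branch_length)

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []

    def newick(self) -> str:
        return self._fmt() + ";"

    def _fmt(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._fmt()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree in Newick format.

    Ties in the Q matrix break to the lowest taxon-index pair; negative branch
    lengths are clamped to zero with the deficit moved to the sister branch.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    nodes = [_Node(name=t) for t in dm.taxa]
    d = dm.d.copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: scan rows in order, take first minimum
        best = (0, 1)
        best_q = np.inf
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best_q - 1e-12:
                    best_q = q[a, b]
                    best = (a, b)
        a, b = best
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        i_glob, j_glob = active[a], active[b]
        new = _Node(children=[(nodes[i_glob], li), (nodes[j_glob], lj)])
        # distances from the new node to the remaining taxa
        d_new = 0.5 * (d[i_glob] + d[j_glob] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d_new
        d[:-1, -1] = d_new
        d[-1, -1] = 0.0
        nodes.append(new)
        active = [x for x in active if x not in (i_glob, j_glob)] + [len(nodes) - 1]

    # resolve the last three nodes with the three-point formulas
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return root.newick()


def groupwise_fst(table: BreedFrequencyTable, groups: dict[str, list[str]],
                  pairs: list[tuple[str, str]] | None = None,
                  min_callrate: float = 0.90,
                  se_method: str = "jackknife") -> pd.DataFrame:
    """Genome-wide FST per group pair: unweighted locus mean and standard error.

    A locus qualifies for a pair when the allele call-rate (called alleles over
    the per-breed maximum observed) reaches ``min_callrate`` in both groups.
    ``se_method``: 'jackknife' (leave-one-chromosome-out, robust to local
    correlation) or 'locus' (plain SE of the per-locus mean).
    """
    for g, breeds in groups.items():
        unknown = set(breeds) - set(table.breeds)
        if unknown:
            raise ValueError(f"group {g!r} lists unknown breeds: {sorted(unknown)}")
    if pairs is None:
        names = list(groups)
        pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    for g1, g2 in pairs:
        if set(groups[g1]) & set(groups[g2]):
            raise ValueError(f"groups {g1!r} and {g2!r} overlap")

    n_max = np.nanmax(np.where(table.n_alleles > 0, table.n_alleles, np.nan), axis=0)
    rows = []
    for g1, g2 in pairs:
        stats_pair = {}
        for g in (g1, g2):
            idx = [table.breed_index(b) for b in groups[g]]
            n = table.n_alleles[:, idx]
            f = table.freq[:, idx]
            tot = n.sum(axis=1)
            ref = np.nansum(np.where(np.isnan(f), 0.0, f) * n, axis=1)
            cap = n_max[idx].sum()
            stats_pair[g] = (np.where(tot > 0, ref / np.maximum(tot, 1), np.nan), tot, tot / cap)
        p1, n1, cr1 = stats_pair[g1]
        p2, n2, cr2 = stats_pair[g2]
        ok = (cr1 >= min_callrate) & (cr2 >= min_callrate) & (n1 >= 1) & (n2 >= 1)
        if not ok.any():
            raise ValueError(f"no qualifying loci for pair ({g1}, {g2})")
        fst = fst_locus(p1[ok], n1[ok], p2[ok], n2[ok])
        chroms = table.loci.loc[ok, "chrom"].to_numpy()
        val = ~np.isnan(fst)
        fst, chroms = fst[val], chroms[val]
        mean = float(fst.mean())
        if se_method == "jackknife":
            uniq = np.unique(chroms)
            if len(uniq) < 2:
                se = float("nan")
            else:
                thetas = np.array([fst[chroms != c].mean() for c in uniq])
                mjack = len(uniq)
                se = float(np.sqrt((mjack - 1) / mjack * ((thetas - thetas.mean()) ** 2).sum()))
        elif se_method == "locus":
            se = float(fst.std(ddof=1) / np.sqrt(len(fst)))
        else:
            raise ValueError("se_method must be 'jackknife' or 'locus'")
        rows.append((g1, g2, mean, se, int(len(fst))))
    return pd.DataFrame(rows, columns=["group1", "group2", "fst", "se", "n_loci"])


def fst_matrix_frame(results: pd.DataFrame, groups: list[str]) -> pd.DataFrame:
    """Square group matrix: FST estimates above the diagonal, SEs below."""
    mat = pd.DataFrame(np.nan, index=groups, columns=groups)
    for _, row in results.iterrows():
        i, j = groups.index(row["group1"]), groups.index(row["group2"])
        a, b = (i, j) if i < j else (j, i)
        mat.iloc[a, b] = row["fst"]
        mat.iloc[b, a] = row["se"]
    return mat
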