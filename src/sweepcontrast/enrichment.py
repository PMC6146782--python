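"""Gene annotation of sweep regions and GO over-representation testing.

For every GO term with at least one gene inside a sweep region, a 2x2
contingency table over the annotated gene universe is tested with a one-sided
Fisher's exact test, and fold enrichment is computed as

    FE = a / [ (a+b)(a+c) / (a+b+c+d) ]

with a = genes in sweeps and in the term, b = in sweeps only, c = in term
only, d = neither. Because genes cluster on chromosomes, Fisher p-values are
calibrated against a positional null: the whole sweep-region set is shifted
along the genome (treated as a circle of concatenated chromosomes) by a
random offset, preserving region sizes and count, genes are re-annotated, and
per-term p-values recomputed. The per-term significance threshold is the 5%
quantile of the permuted p-values; a term is significant when its observed
p lies strictly below that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import regions as rg


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # in sweep and in term
    b: int  # in sweep, not in term
    c: int  # in term, not in sweep
    d: int  # neither

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def read_gene_intervals(path, fmt: str | None = None) -> pd.DataFrame:
    """Gene intervals from BED (0-based) or minimal GFF3 gene lines (1-based).

    Returns a frame gene_id/chrom/start/end on 0-based half-open coordinates;
    strand is ignored.
    """
    path = str(path)
    if fmt is None:
        fmt = "gff3" if path.endswith((".gff", ".gff3")) else "bed"
    if fmt == "bed":
        df = rg.read_bed(path)
        if "name" not in df.columns:
            raise ValueError("gene BED needs a 4th (name) column")
        return df.rename(columns={"name": "gene_id"})[["gene_id", "chrom", "start", "end"]]
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"gene feature without ID attribute: {line.strip()}")
            rows.append((gid.removeprefix("gene:"), f[0], int(f[3]) - 1, int(f[4])))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def read_go_map(path) -> pd.DataFrame:
    """Two-column TSV gene_id -> GO term (one row per pair)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("GO map needs two columns: gene_id, term")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "term"]
    return df.drop_duplicates()


def genes_in_regions(regions_df: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    """Gene ids overlapping any region by >= 1 bp (any-overlap rule)."""
    if not len(regions_df) or not len(genes):
        return set()
    hit = rg.overlaps_any(genes.rename(columns={"gene_id": "name"}), regions_df)
    return set(genes.loc[hit, "gene_id"])


def fisher_p(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher's exact test p-value for over-representation.

    One-sided 'greater' is the hypergeometric upper tail P(X >= a) with
    X ~ Hypergeom(N, K=a+c, n=a+b); 'two-sided' is available via flag.
    """
    if table.n < 1:
        raise ValueError("empty contingency table")
    if alternative == "greater":
        return float(stats.hypergeom.sf(table.a - 1, table.n, table.a + table.c, table.a + table.b))
    if alternative == "two-sided":
        _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="two-sided")
        return float(p)
    raise ValueError("alternative must be 'greater' or 'two-sided'")


def fold_enrichment(table: ContingencyTable) -> float:
    """FE = a / [(a+b)(a+c)/N]; raises when a margin is empty."""
    if (table.a + table.b) == 0 or (table.a + table.c) == 0:
        raise ValueError("fold enrichment undefined: empty margin")
    expected = (table.a + table.b) * (table.a + table.c) / table.n
    return table.a / expected


def _circle_layout(genome_lengths: dict[str, int]):
    offsets = {}
    total = 0
    for chrom, length in genome_lengths.items():
        offsets[chrom] = total
        total += int(length)
    return offsets, total


def _to_circle(df: pd.DataFrame, offsets: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    off = df["chrom"].map(offsets)
    if off.isna().any():
        raise ValueError("interval on chromosome absent from genome_lengths")
    off = off.to_numpy(dtype=np.int64)
    return df["start"].to_numpy() + off, df["end"].to_numpy() + off


def _overlap_mask(gs: np.ndarray, ge: np.ndarray, rs: np.ndarray, re_: np.ndarray,
                  total: int) -> np.ndarray:
    """Which [gs, ge) intervals overlap any shifted region, with wrap-around."""
    pieces = []
    for s, e in zip(rs, re_):
        if e <= total:
            pieces.append((s, e))
        else:  # wrapped region: split into two circle pieces
            pieces.append((s, total))
            pieces.append((0, e - total))
    pieces.sort()
    # merge
    ms, me = [], []
    for s, e in pieces:
        if ms and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    ms = np.array(ms)
    me = np.array(me)
    idx = np.searchsorted(me, gs, side="right")
    hit = (idx < len(ms)) & (ms[np.minimum(idx, len(ms) - 1)] < ge)
    return hit


def shift_permutation(regions_df: pd.DataFrame, genes: pd.DataFrame, go_map: pd.DataFrame,
                      genome_lengths: dict[str, int], B: int = 5000,
                      seed: int | np.random.Generator = 0,
                      alternative: str = "greater") -> tuple[pd.Series, pd.DataFrame]:
    """Circular-shift permutation null for GO over-representation.

    Returns ``(observed_p, permuted)`` where ``observed_p`` is a Series of
    Fisher p-values indexed by term (terms with >= 1 gene in the observed
    sweep regions) and ``permuted`` is a (B x terms) frame of p-values under
    random genome shifts. Each replicate shifts every region by one shared
    uniform offset in [1, genome length] on the concatenated chromosome
    circle (wrap-around), preserving region sizes and count.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if hasattr(seed, "integers") else np.random.default_rng(seed)
    offsets, total = _circle_layout(genome_lengths)
    gs, ge = _to_circle(genes, offsets)
    rs, re_ = _to_circle(regions_df[rg.REGION_COLUMNS], offsets)
    base_len = int((re_ - rs).sum())
    gene_ids = genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    gid_index = {g: i for i, g in enumerate(gene_ids)}

    obs_mask = _overlap_mask(gs, ge, rs, re_, total)
    obs_genes = set(gene_ids[obs_mask])

    gm = go_map[go_map["gene_id"].isin(gid_index)]
    terms_all = gm.groupby("term")["gene_id"].apply(list)
    # terms observed in the unshifted annotation
    terms = [t for t, members in terms_all.items() if obs_genes & set(members)]
    term_matrix = np.zeros((len(terms), n_genes), dtype=bool)
    for ti, t in enumerate(terms):
        for g in terms_all[t]:
            term_matrix[ti, gid_index[g]] = True
    K = term_matrix.sum(axis=1)

    term_matrix_int = term_matrix.astype(np.int64)

    def term_pvals(mask: np.ndarray) -> np.ndarray:
        n_in = int(mask.sum())
        a = term_matrix_int @ mask.astype(np.int64)
        if alternative == "greater":
            return stats.hypergeom.sf(a - 1, n_genes, K, n_in)
        return np.array([
            fisher_p(ContingencyTable(int(ai), n_in - int(ai), int(Ki) - int(ai),
                                      n_genes - n_in - int(Ki) + int(ai)), alternative)
            for ai, Ki in zip(a, K)
        ])

    observed = pd.Series(term_pvals(obs_mask), index=terms, name="fisher_p")

    perm = np.empty((B, len(terms)))
    for b in range(B):
        offset = int(rng.integers(1, total + 1))
        srs = (rs + offset) % total
        sre = srs + (re_ - rs)
        assert int((sre - srs).sum()) == base_len and len(srs) == len(rs)
        mask = _overlap_mask(gs, ge, srs, sre, total)
        perm[b] = term_pvals(mask)
    permuted = pd.DataFrame(perm, columns=terms)
    return observed, permuted


def empirical_significance(observed_p: pd.Series, permuted: pd.DataFrame,
                           q: float = 0.05) -> pd.DataFrame:
    """Per-term empirical thresholds and significance calls.

    The threshold is the q-quantile (linear interpolation, type 7) of the
    term's permuted p-values; a term is significant when its observed p is
    strictly below its threshold. An empirical rank p-value
    (1 + #{perm <= obs}) / (B + 1) is reported alongside.
    """
    rows = []
    for term in observed_p.index:
        samples = permuted[term].to_numpy()
        if not len(samples):
            raise ValueError(f"no permuted samples for term {term!r}")
        thr = float(np.quantile(samples, q))
        obs = float(observed_p[term])
        rank_p = (1.0 + float((samples <= obs).sum())) / (len(samples) + 1.0)
        rows.append((term, obs, thr, rank_p, obs < thr))
    return pd.DataFrame(rows, columns=["term", "fisher_p", "empirical_threshold",
                                       "empirical_p", "significant"])


def enrichment_table(regions_df: pd.DataFrame, genes: pd.DataFrame, go_map: pd.DataFrame,
                     genome_lengths: dict[str, int], B: int = 5000,
                     seed: int | np.random.Generator = 0, q: float = 0.05) -> pd.DataFrame:
    """Full over-representation analysis; one row per tested term.

    Columns mirror the usual reporting layout: term, Fisher p, empirical
    threshold and rank p, genes in term and sweep, fold enrichment,
    significance flag.
    """
    observed, permuted = shift_permutation(regions_df, genes, go_map, genome_lengths, B, seed)
    result = empirical_significance(observed, permuted, q)
    sweep_genes = genes_in_regions(regions_df, genes)
    gm = go_map[go_map["gene_id"].isin(set(genes["gene_id"]))]
    n_univ = genes["gene_id"].nunique()
    a_col, fe_col = [], []
    for term in result["term"]:
        members = set(gm.loc[gm["term"] == term, "gene_id"])
        a = len(members & sweep_genes)
        b = len(sweep_genes) - a
        c = len(members) - a
        d = n_univ - a - b - c
        a_col.append(a)
        fe_col.append(fold_enrichment(ContingencyTable(a, b, c, d)))
    result["genes_in_term_and_sweep"] = a_col
    result["fold_enrichment"] = fe_col
    return result.sort_values("empirical_p").reset_index(drop=True)
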