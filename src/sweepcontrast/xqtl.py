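"""X-linked haplotype QTL analysis in an F2 intercross.

A large-pig x minipig F2 design segregates two anciently diverged, effectively
non-recombining X haplotypes. SNP-chip genotypes in the sweep interval are
filtered, diagnostic ("informative") markers — fixed for different alleles in
the two founder groups — are identified, and each F2 animal is assigned one of
three haplotype classes: (1) homozygous females / hemizygous males carrying
the large-pig haplotype, (2) heterozygous females, (3) hemizygous males
carrying the minipig haplotype. Size traits are analysed with a fixed-effects
linear model

    y = B + S + b1*A + b2*A^2 + H(S) + B*S + b3*(B*A) + b4*(B*A^2)
        + B*H(S) + b5*(A*H(S)) + e

(B founder-dam breed, S sex, A age in days, H haplotype class nested in sex),
reduced by stepwise backward elimination under marginality, followed by
least-squares means and unadjusted pairwise (LSD) comparisons for H(S).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class ChipGenotypes:
    """SNP-array genotypes as alt-allele dosages.

    ``geno`` is (samples x snps): females 0/1/2, hemizygous males 0/1, NaN
    missing. ``ploidy`` per sample (2 females, 1 males on X). ``generation``
    in {P0, F1, F2}; ``group`` is the founder-group label (e.g. 'large',
    'minipig') for P0 animals, '' otherwise.
    """

    samples: tuple[str, ...]
    snp_ids: tuple[str, ...]
    chrom: np.ndarray
    pos: np.ndarray
    geno: np.ndarray
    ploidy: np.ndarray
    sex: tuple[str, ...]
    generation: tuple[str, ...]
    group: tuple[str, ...]

    def subset(self, sample_mask=None, snp_mask=None) -> "ChipGenotypes":
        sm_ = np.ones(len(self.samples), bool) if sample_mask is None else np.asarray(sample_mask)
        kp = np.ones(len(self.snp_ids), bool) if snp_mask is None else np.asarray(snp_mask)
        take = lambda seq, m: tuple(x for x, keep in zip(seq, m) if keep)
        return ChipGenotypes(
            samples=take(self.samples, sm_), snp_ids=take(self.snp_ids, kp),
            chrom=self.chrom[kp], pos=self.pos[kp],
            geno=self.geno[np.ix_(sm_, kp)], ploidy=self.ploidy[sm_],
            sex=take(self.sex, sm_), generation=take(self.generation, sm_),
            group=take(self.group, sm_),
        )


def write_chip(chip: ChipGenotypes, geno_path, map_path) -> None:
    """Write chip genotypes as a sample x SNP dosage TSV plus a SNP map TSV."""
    df = pd.DataFrame(chip.geno, columns=list(chip.snp_ids))
    df.insert(0, "sample_id", list(chip.samples))
    df.insert(1, "sex", list(chip.sex))
    df.insert(2, "generation", list(chip.generation))
    df.insert(3, "group", list(chip.group))
    df.to_csv(geno_path, sep="\t", index=False, na_rep="NA")
    pd.DataFrame({"snp_id": list(chip.snp_ids), "chrom": chip.chrom, "pos": chip.pos}
                 ).to_csv(map_path, sep="\t", index=False)


def read_chip(geno_path, map_path) -> ChipGenotypes:
    """Read the TSV pair written by :func:`write_chip`.

    Dosages are alt-allele counts (females 0/1/2, males on X 0/1, NA missing);
    male ploidy is 1, the X-region convention of this analysis.
    """
    df = pd.read_csv(geno_path, sep="\t", dtype={"sample_id": str})
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    meta_cols = ["sample_id", "sex", "generation", "group"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise ValueError(f"chip genotype TSV missing columns: {sorted(missing)}")
    snp_ids = [c for c in df.columns if c not in meta_cols]
    if set(snp_ids) != set(snp_map["snp_id"]):
        raise ValueError("SNP columns do not match the map file")
    snp_map = snp_map.set_index("snp_id").loc[snp_ids]
    sex = tuple(df["sex"])
    return ChipGenotypes(
        samples=tuple(df["sample_id"]), snp_ids=tuple(snp_ids),
        chrom=snp_map["chrom"].to_numpy(), pos=snp_map["pos"].to_numpy(dtype=np.int64),
        geno=df[snp_ids].to_numpy(dtype=float),
        ploidy=np.where(np.array(sex) == "male", 1, 2).astype(np.int64),
        sex=sex, generation=tuple(df["generation"].fillna("")),
        group=tuple(df["group"].fillna("")),
    )


def filter_chip(chip: ChipGenotypes, max_ind_missing: float = 0.90,
                min_snp_callrate: float = 0.90, min_maf: float = 0.01) -> ChipGenotypes:
    """Chip quality filter: individuals first, then SNPs.

    Individuals with a missing-genotype fraction strictly above
    ``max_ind_missing`` are removed; then SNPs with call rate strictly below
    ``min_snp_callrate`` or minor allele frequency strictly below ``min_maf``
    (boundaries pass).
    """
    miss = np.isnan(chip.geno).mean(axis=1)
    keep_ind = miss <= max_ind_missing
    sub = chip.subset(sample_mask=keep_ind)
    called = ~np.isnan(sub.geno)
    callrate = called.mean(axis=0)
    alt = np.where(called, sub.geno, 0.0).sum(axis=0)
    tot = (called * sub.ploidy[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_alt = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    keep_snp = (callrate >= min_snp_callrate) & (maf >= min_maf)
    out = sub.subset(snp_mask=keep_snp)
    if not len(out.samples) or not len(out.snp_ids):
        raise ValueError("chip filtering removed all samples or all SNPs")
    return out


def informative_snps(chip: ChipGenotypes, groups: tuple[str, str] = ("large", "minipig")) -> list[str]:
    """Diagnostic markers: fixed within each founder group, different between.

    Uses the P0 animals of the two groups; a single heterozygous or discordant
    founder disqualifies a marker.
    """
    gen = np.array(chip.generation)
    grp = np.array(chip.group)
    out = []
    for j, snp in enumerate(chip.snp_ids):
        fixed_allele = {}
        ok = True
        for g in groups:
            sel = (gen == "P0") & (grp == g)
            if not sel.any():
                ok = False
                break
            doses = chip.geno[sel, j]
            ploidy = chip.ploidy[sel]
            called = ~np.isnan(doses)
            if not called.any():
                ok = False
                break
            frac = doses[called] / ploidy[called]  # 0, 0.5, or 1 per animal
            if np.any((frac != 0.0) & (frac != 1.0)) or len(set(frac)) != 1:
                ok = False
                break
            fixed_allele[g] = frac[0]
        if ok and fixed_allele[groups[0]] != fixed_allele[groups[1]]:
            out.append(snp)
    return out


UNASSIGNED = 0


def classify_haplotype(chip: ChipGenotypes, informative: list[str],
                       large_group: str = "large", mini_group: str = "minipig",
                       groups_fixed: dict[str, dict[str, float]] | None = None) -> pd.Series:
    """Assign each animal a haplotype class from its informative-marker pattern.

    Classes: 1 = homozygous (females) or hemizygous (males) for the large-pig
    haplotype, 2 = heterozygous females, 3 = hemizygous minipig males.
    Discordant patterns across markers, or animals with no called informative
    marker, are left unassigned (0): with no recombination assumed, a mixed
    pattern flags a genotyping error or recombinant rather than a class.
    """
    if groups_fixed is None:
        gen = np.array(chip.generation)
        grp = np.array(chip.group)
        groups_fixed = {}
        for g in (large_group, mini_group):
            sel = (gen == "P0") & (grp == g)
            alleles = {}
            for snp in informative:
                j = chip.snp_ids.index(snp)
                doses = chip.geno[sel, j]
                pl = chip.ploidy[sel]
                called = ~np.isnan(doses)
                alleles[snp] = float((doses[called] / pl[called])[0])
            groups_fixed[g] = alleles
    idx = [chip.snp_ids.index(s) for s in informative]
    classes = []
    for i, sample in enumerate(chip.samples):
        calls = []
        for snp, j in zip(informative, idx):
            dose = chip.geno[i, j]
            if np.isnan(dose):
                continue
            frac = dose / chip.ploidy[i]
            large_frac = groups_fixed[large_group][snp]
            if frac == large_frac:
                calls.append("L")
            elif frac == groups_fixed[mini_group][snp]:
                calls.append("m")
            else:
                calls.append("H")  # heterozygous (females)
        if not calls or len(set(calls)) != 1:
            classes.append(UNASSIGNED)
            continue
        state = calls[0]
        if chip.sex[i] == "female":
            classes.append({"L": 1, "H": 2, "m": UNASSIGNED}[state])
        else:
            classes.append({"L": 1, "m": 3, "H": UNASSIGNED}[state])
    return pd.Series(classes, index=list(chip.samples), name="hap_class")


def expected_cross_distribution() -> dict[str, dict[str, dict[str, float]]]:
    """Mendelian X-haplotype expectations for the large-dam x minipig-sire design.

    P0 dams contribute the large-pig haplotype (L), sires the minipig one (m);
    with no recombination: F1 females all Lm, F1 males all L; F2 females half
    LL, half Lm; F2 males half L, half m.
    """
    return {
        "F1": {"female": {"Lm": 1.0}, "male": {"L": 1.0}},
        "F2": {"female": {"LL": 0.5, "Lm": 0.5}, "male": {"L": 0.5, "m": 0.5}},
    }


# --- fixed-effects size model ------------------------------------------------

FULL_MODEL_TERMS = ("B", "S", "A", "A2", "HS", "B:S", "B:A", "B:A2", "B:HS", "A:HS")

# marginality: term -> set of terms it contains (may not be dropped while present)
_CONTAINS = {
    "B": set(), "S": set(), "A": set(), "A2": {"A"}, "HS": {"S"},
    "B:S": {"B", "S"}, "B:A": {"B", "A"}, "B:A2": {"B", "A", "A2"},
    "B:HS": {"B", "S", "HS"}, "A:HS": {"A", "S", "HS"},
}


@dataclass
class ModelFit:
    trait: str
    retained: tuple[str, ...]
    term_pvalues: dict[str, float]
    results: object          # statsmodels RegressionResults of the final model
    design_info: dict = field(repr=False, default_factory=dict)

    @property
    def residual_variance(self) -> float:
        return float(self.results.mse_resid)


def _hs_levels(df: pd.DataFrame) -> list[tuple[str, int]]:
    return sorted(set(zip(df["sex"], df["hap_class"])))


def _term_columns(term: str, df: pd.DataFrame, means: dict) -> pd.DataFrame:
    """Design columns for one model term (treatment coding, first level reference)."""
    breeds = sorted(df["founder_dam_breed"].unique())
    sexes = sorted(df["sex"].unique())
    a = df["age_days"].to_numpy(dtype=float) - means["age_mean"]
    cols = {}
    if term == "A":
        cols["A"] = a
    elif term == "A2":
        cols["A2"] = a ** 2
    elif term == "B":
        for b in breeds[1:]:
            cols[f"B[{b}]"] = (df["founder_dam_breed"] == b).astype(float).to_numpy()
    elif term == "S":
        for s in sexes[1:]:
            cols[f"S[{s}]"] = (df["sex"] == s).astype(float).to_numpy()
    elif term == "HS":
        # haplotype nested in sex: per sex, dummies for classes beyond the first
        for s in sexes:
            lv = sorted(df.loc[df["sex"] == s, "hap_class"].unique())
            for h in lv[1:]:
                cols[f"HS[{s}:{h}]"] = ((df["sex"] == s) & (df["hap_class"] == h)).astype(float).to_numpy()
    elif ":" in term:
        left, right = term.split(":")
        lcols = _term_columns(left, df, means)
        rcols = _term_columns(right, df, means)
        for ln, lv in lcols.items():
            for rn, rv in rcols.items():
                cols[f"{ln}*{rn}"] = lv * rv
    else:
        raise ValueError(f"unknown term {term!r}")
    return pd.DataFrame(cols, index=df.index)


def _build_design(df: pd.DataFrame, terms: tuple[str, ...], means: dict) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for t in terms:
        X = pd.concat([X, _term_columns(t, df, means)], axis=1)
    return X


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, X).fit()


def fit_size_model(records: pd.DataFrame, trait: str, alpha: float = 0.05,
                   always_keep: tuple[str, ...] = ()) -> ModelFit:
    """Fit the full fixed-effects model and reduce it by backward elimination.

    ``records`` needs columns founder_dam_breed, sex, age_days, hap_class and
    the trait; unassigned haplotype classes are excluded. At each step the
    removable term (not contained in any retained term, not in ``always_keep``)
    with the largest partial-F p-value above ``alpha`` is dropped; ties break
    to the later term in the declared order. Marginality is respected:
    interactions are removed before their contained main effects.
    """
    df = records.loc[records["hap_class"] != UNASSIGNED].copy()
    df = df.dropna(subset=[trait, "age_days", "sex", "founder_dam_breed", "hap_class"])
    for col in ("founder_dam_breed", "sex"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    y = df[trait].to_numpy(dtype=float)
    means = {"age_mean": float(df["age_days"].mean())}

    terms = list(FULL_MODEL_TERMS)
    X = _build_design(df, tuple(terms), means)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by QR pivoting
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8] if r.shape[0] >= X.shape[1] else []
        raise ValueError(f"rank-deficient design (aliased columns: {bad or 'unresolved'})")

    def term_pvalue(current: list[str], term: str) -> float:
        Xf = _build_design(df, tuple(current), means)
        full = _fit_ols(y, Xf)
        reduced_terms = [t for t in current if t != term]
        Xr = _build_design(df, tuple(reduced_terms), means)
        red = _fit_ols(y, Xr)
        df_diff = Xf.shape[1] - Xr.shape[1]
        if df_diff <= 0:
            return 1.0
        f = ((red.ssr - full.ssr) / df_diff) / full.mse_resid
        return float(stats.f.sf(f, df_diff, full.df_resid))

    while True:
        removable = [t for t in terms
                     if t not in always_keep
                     and not any(t in _CONTAINS[other] for other in terms if other != t)]
        if not removable:
            break
        pvals = {t: term_pvalue(terms, t) for t in removable}
        worst = max(removable, key=lambda t: (pvals[t], terms.index(t)))
        if pvals[worst] > alpha:
            terms.remove(worst)
        else:
            break

    final_p = {}
    for t in terms:
        final_p[t] = term_pvalue(terms, t)
    Xf = _build_design(df, tuple(terms), means)
    res = _fit_ols(y, Xf)
    info = {"data": df, "means": means, "trait": trait,
            "breeds": sorted(df["founder_dam_breed"].unique()),
            "sexes": sorted(df["sex"].unique())}
    return ModelFit(trait=trait, retained=tuple(terms), term_pvalues=final_p,
                    results=res, design_info=info)


def _lsmean_row(fit: ModelFit, sex: str, hap: int) -> pd.Series:
    """Design row for an LS-mean: factors balanced, covariates at their means."""
    df = fit.design_info["data"]
    means = fit.design_info["means"]
    X = _build_design(df, fit.retained, means)
    row = pd.Series(0.0, index=X.columns)
    row["Intercept"] = 1.0
    a_mean = 0.0  # age is centred, so its balanced value is 0
    a2_mean = float((df["age_days"] - means["age_mean"]).pow(2).mean())
    breeds = fit.design_info["breeds"]
    n_b = len(breeds)
    for col in X.columns:
        if col == "Intercept":
            continue
        parts = col.split("*")
        val = 1.0
        for part in parts:
            if part == "A":
                val *= a_mean
            elif part == "A2":
                val *= a2_mean
            elif part.startswith("B["):
                val *= 1.0 / n_b  # balanced over breeds
            elif part.startswith("S["):
                level = part[2:-1]
                val *= 1.0 if level == sex else 0.0
            elif part.startswith("HS["):
                s, h = part[3:-1].split(":")
                val *= 1.0 if (s == sex and int(h) == hap) else 0.0
            else:
                raise ValueError(f"unrecognised design column {part!r}")
        row[col] = val
    return row


def ls_means(fit: ModelFit, term: str = "HS") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Least-squares means and pairwise LSD comparisons for the H(S) levels.

    Returns ``(means, comparisons)``: adjusted means with standard errors per
    (sex, class) level, and all pairwise t-tests without multiplicity
    adjustment (least significant difference).
    """
    if term != "HS" or "HS" not in fit.retained:
        raise ValueError(f"term {term!r} not retained in the fit")
    df = fit.design_info["data"]
    levels = _hs_levels(df)
    beta = fit.results.params
    cov = fit.results.cov_params()
    rows = []
    lrows = {}
    for sex, hap in levels:
        L = _lsmean_row(fit, sex, hap)
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        rows.append((sex, hap, est, se))
        lrows[(sex, hap)] = L
    means = pd.DataFrame(rows, columns=["sex", "hap_class", "lsmean", "se"])
    comps = []
    dof = fit.results.df_resid
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            Ld = lrows[levels[i]] - lrows[levels[j]]
            est = float(Ld @ beta)
            se = float(np.sqrt(Ld @ cov @ Ld))
            t = est / se if se > 0 else 0.0
            p = 2.0 * float(stats.t.sf(abs(t), dof))
            comps.append((levels[i], levels[j], est, se, t, p))
    comparisons = pd.DataFrame(comps, columns=["level1", "level2", "diff", "se", "t", "p"])
    return means, comparisons
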