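"""SNP filtering and population-genetic statistics for biallelic panels.

Genotypes are alternate-allele dosages (0/1/2, NaN = missing) for
individuals x loci, with an individual -> population map and optional
population coordinates and per-locus assay metadata (reproducibility, call
rate).

Implemented statistics:

* sequential locus filtering by reproducibility, call rate, and minor-allele
  frequency, with an attrition report;
* observed / expected heterozygosity (sample-size-corrected gene diversity)
  and F_IS per population;
* Weir–Cockerham pairwise F_ST (ratio of summed variance components) with a
  bootstrap-over-loci p-value;
* Weir–Goudet population-specific F_ST ("betas") from allele-matching
  proportions;
* distance-based AMOVA on dosage vectors with three strata (among
  populations / among individuals within populations / within individuals)
  and a label-permutation test;
* Nei (1972) standard genetic distance between populations;
* Mantel isolation-by-distance test (linearized F_ST vs great-circle km);
* Kosman–Leonard inter-individual distance (fraction of unshared alleles
  per locus, averaged over jointly genotyped loci);
* private-allele counts and dosage PCA.

Negative variance components and negative F estimates are reported as
computed, never truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# container and I/O


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x loci) with population structure."""

    genotypes: pd.DataFrame  # float, entries 0/1/2/NaN
    populations: pd.Series  # index = individuals
    coords: pd.DataFrame | None = None  # index = population; lat, lon
    metadata: pd.DataFrame | None = None  # index = locus; reproducibility, call_rate

    def __post_init__(self):
        self.genotypes = self.genotypes.astype(float)
        vals = self.genotypes.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype entries must be 0, 1, 2 or missing")
        self.populations = pd.Series(self.populations).reindex(self.genotypes.index)
        if self.populations.isna().any():
            bad = self.populations.index[self.populations.isna()].tolist()
            raise ValueError(f"individuals without a population: {bad}")

    @property
    def individuals(self) -> list:
        return list(self.genotypes.index)

    @property
    def loci(self) -> list:
        return list(self.genotypes.columns)

    @property
    def pop_names(self) -> list:
        return sorted(self.populations.unique())

    def pop_indices(self) -> dict[str, np.ndarray]:
        pops = self.populations.to_numpy()
        return {p: np.flatnonzero(pops == p) for p in self.pop_names}

    def missing_fraction(self) -> float:
        return float(self.genotypes.isna().to_numpy().mean())

    def subset_loci(self, loci) -> "GenotypePanel":
        md = self.metadata.loc[loci] if self.metadata is not None else None
        return GenotypePanel(
            self.genotypes[loci], self.populations, self.coords, md
        )


def read_dosage_csv(geno_path, popmap_path, metadata_path=None) -> GenotypePanel:
    """Assemble a panel from CSV files.

    * genotypes: rows = individuals (first column = id), columns = loci;
    * population map: individual_id, population[, lat, lon] — coordinates
      are taken per population from its first row;
    * locus metadata (optional): locus_id, reproducibility, call_rate.
    """
    geno = pd.read_csv(geno_path, index_col=0)
    popmap = pd.read_csv(popmap_path)
    populations = popmap.set_index("individual_id")["population"]
    coords = None
    if {"lat", "lon"}.issubset(popmap.columns):
        coords = (
            popmap.groupby("population")[["lat", "lon"]].first().astype(float)
        )
    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, index_col="locus_id")
    return GenotypePanel(geno, populations, coords, metadata)


def read_vcf(vcf_path, popmap_path) -> GenotypePanel:
    """Read biallelic SNPs from a VCF into a dosage panel (cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rows, names = [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    dosage_map = np.array([0.0, 1.0, np.nan, 2.0])
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        rows.append(dosage_map[variant.gt_types])
        names.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    geno = pd.DataFrame(np.array(rows).T, index=samples, columns=names)
    popmap = pd.read_csv(popmap_path)
    populations = popmap.set_index("individual_id")["population"]
    coords = None
    if {"lat", "lon"}.issubset(popmap.columns):
        coords = popmap.groupby("population")[["lat", "lon"]].first().astype(float)
    return GenotypePanel(geno, populations, coords, None)


# ---------------------------------------------------------------------------
# filtering


def filter_loci(
    panel: GenotypePanel,
    repro_min: float = 0.98,
    callrate_min: float = 0.95,
    maf_min: float = 0.02,
) -> tuple[GenotypePanel, dict]:
    """Sequential locus filters: reproducibility, call rate, then MAF.

    A locus is kept when its statistic is >= the threshold.  The minor-allele
    threshold is interpreted on the *frequency* scale (a fractional count is
    not meaningful); the report flags this interpretation.  Returns the
    filtered panel and an attrition report.
    """
    for name, t in (("repro_min", repro_min), ("callrate_min", callrate_min), ("maf_min", maf_min)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    geno = panel.genotypes
    report = {
        "n_loci_input": geno.shape[1],
        "n_individuals": geno.shape[0],
        "maf_threshold_note": "minor-allele threshold applied as a frequency",
        "steps": [],
    }

    keep = pd.Series(True, index=geno.columns)
    if panel.metadata is not None and "reproducibility" in panel.metadata:
        repro = panel.metadata["reproducibility"].reindex(geno.columns)
        keep &= repro >= repro_min
    n_after = int(keep.sum())
    report["steps"].append(
        {"filter": "reproducibility", "threshold": repro_min,
         "removed": report["n_loci_input"] - n_after, "remaining": n_after}
    )

    sub = geno.loc[:, keep]
    call_rate = 1.0 - sub.isna().mean(axis=0)
    keep2 = call_rate >= callrate_min
    n_prev, n_after = n_after, int(keep2.sum())
    report["steps"].append(
        {"filter": "call_rate", "threshold": callrate_min,
         "removed": n_prev - n_after, "remaining": n_after}
    )

    sub = sub.loc[:, keep2]
    p = sub.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep3 = maf >= maf_min
    n_prev, n_after = n_after, int(keep3.sum())
    report["steps"].append(
        {"filter": "maf", "threshold": maf_min,
         "removed": n_prev - n_after, "remaining": n_after}
    )
    if n_after == 0:
        raise ValueError(f"all loci removed; attrition: {report['steps']}")

    out = panel.subset_loci(list(sub.columns[keep3]))
    report["n_loci_output"] = n_after
    report["missing_pct"] = 100.0 * out.missing_fraction()
    return out, report


# ---------------------------------------------------------------------------
# heterozygosity


def _pop_locus_arrays(panel: GenotypePanel):
    """Per population: (n genotyped, alt-allele freq, het freq) per locus."""
    g = panel.genotypes.to_numpy()
    out = {}
    for pop, idx in panel.pop_indices().items():
        sub = g[idx]
        n = np.sum(~np.isnan(sub), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * np.where(n > 0, n, np.nan))
            h = np.nansum(sub == 1.0, axis=0) / np.where(n > 0, n, np.nan)
        out[pop] = (n, p, h)
    return out


def heterozygosities(panel: GenotypePanel, per_locus: bool = False):
    """Observed/expected heterozygosity and F_IS per population.

    Per locus, H_O is the heterozygote proportion among genotyped
    individuals and H_E the sample-size-corrected gene diversity
    ``Hs = n/(n-1) * (1 - p^2 - q^2 - H_O/(2n))``.  The summary averages
    both over loci with at least two genotyped individuals and reports
    ``F_IS = 1 - mean(H_O)/mean(H_E)`` (NaN when mean H_E is 0).
    """
    stats = _pop_locus_arrays(panel)
    rows = {}
    detail = {}
    for pop, (n, p, h) in stats.items():
        valid = n >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            hs = (n / (n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2 - h / (2.0 * n))
        ho_mean = float(np.nanmean(np.where(valid, h, np.nan)))
        he_mean = float(np.nanmean(np.where(valid, hs, np.nan)))
        fis = 1.0 - ho_mean / he_mean if he_mean > 0 else np.nan
        if he_mean == 0:
            warnings.warn(f"population {pop!r} is monomorphic; F_IS undefined")
        rows[pop] = {
            "n": int(len(panel.populations[panel.populations == pop])),
            "Ho": ho_mean,
            "He": he_mean,
            "Fis": fis,
        }
        if per_locus:
            detail[pop] = pd.DataFrame(
                {"n": n, "p": p, "Ho": h, "He": hs}, index=panel.loci
            )
    summary = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return (summary, detail) if per_locus else summary


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir–Cockerham (1984) per-locus variance components a, b, c.

    ``n``, ``p``, ``h``: (r, L) arrays of sample sizes (genotyped
    individuals), alt-allele frequencies, and heterozygote frequencies for
    r populations.  Loci unusable for the estimator (fewer than two
    populations with data, or mean sample size <= 1) return NaN components.
    """
    r = n.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        npops = (n > 0).sum(axis=0)
        nc = (n.sum(axis=0) - (n**2).sum(axis=0) / n.sum(axis=0)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = (npops < 2) | (nbar <= 1.0) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst(panel: GenotypePanel, pops: list | None = None) -> float:
    """Multilocus Weir–Cockerham theta over the given (default all) pops."""
    stats = _pop_locus_arrays(panel)
    pops = pops or panel.pop_names
    n = np.array([stats[p][0] for p in pops])
    p_ = np.array([stats[p][1] for p in pops])
    h = np.array([stats[p][2] for p in pops])
    p_ = np.nan_to_num(p_)
    h = np.nan_to_num(h)
    a, b, c = _wc_components(n, p_, h)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    return float(num / den) if den != 0 else np.nan


def pairwise_fst(
    panel: GenotypePanel, n_boot: int = 1000, seed=None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pairwise multilocus Weir–Cockerham F_ST with bootstrap p-values.

    The p-value for a pair is the one-sided bootstrap-over-loci probability
    (with +1 correction) that theta <= 0.  Populations with a single
    individual are excluded with a warning.  ``n_boot=0`` skips inference.
    """
    sizes = panel.populations.value_counts()
    usable = sorted(sizes.index[sizes >= 2])
    dropped = sorted(set(panel.pop_names) - set(usable))
    if dropped:
        warnings.warn(f"excluding single-individual populations: {dropped}")
    if len(usable) < 2:
        raise ValueError("need at least two populations with >= 2 individuals")

    stats = _pop_locus_arrays(panel)
    rng = np.random.default_rng(seed)
    fst = pd.DataFrame(0.0, index=usable, columns=usable)
    pvals = pd.DataFrame(np.nan, index=usable, columns=usable) if n_boot else None
    for i, pa in enumerate(usable):
        for pb in usable[i + 1:]:
            n = np.array([stats[pa][0], stats[pb][0]])
            p_ = np.nan_to_num(np.array([stats[pa][1], stats[pb][1]]))
            h = np.nan_to_num(np.array([stats[pa][2], stats[pb][2]]))
            a, b, c = _wc_components(n, p_, h)
            ok = np.isfinite(a + b + c)
            a, d = a[ok], (a + b + c)[ok]
            theta = float(a.sum() / d.sum()) if d.sum() != 0 else np.nan
            fst.loc[pa, pb] = fst.loc[pb, pa] = theta
            if n_boot:
                L = a.size
                hits = 0
                chunk = max(1, min(n_boot, int(2e7 // max(L, 1))))
                done = 0
                while done < n_boot:
                    m = min(chunk, n_boot - done)
                    idx = rng.integers(0, L, size=(m, L))
                    th = a[idx].sum(axis=1) / d[idx].sum(axis=1)
                    hits += int((th <= 0).sum())
                    done += m
                pvals.loc[pa, pb] = pvals.loc[pb, pa] = (1.0 + hits) / (n_boot + 1.0)
    return fst, pvals


def population_specific_fst(panel: GenotypePanel) -> pd.Series:
    """Weir–Goudet population-specific F_ST estimates ("betas").

    ``beta_i = 1 - (1 - M_i) / (1 - M_B)`` as a ratio of locus sums, where
    ``M_i`` is the unbiased within-population allele-matching proportion of
    population i and ``M_B`` the average between-population matching over
    all population pairs.  Values may be negative.
    """
    pops = panel.pop_names
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    stats = _pop_locus_arrays(panel)
    L = len(panel.loci)
    r = len(pops)

    # within matching per pop per locus (unbiased), allele counts n_al = 2n
    M_w = np.full((r, L), np.nan)
    P = np.full((r, L), np.nan)
    for k, pop in enumerate(pops):
        n, p, _h = stats[pop]
        nal = 2.0 * n
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = p**2 + (1.0 - p) ** 2
            M_w[k] = (nal * raw - 1.0) / (nal - 1.0)
        M_w[k, n < 1] = np.nan
        P[k] = p
    # between matching, averaged over unordered pop pairs
    pair_sum = np.zeros(L)
    pair_cnt = np.zeros(L)
    for i in range(r):
        for j in range(i + 1, r):
            m_ij = P[i] * P[j] + (1 - P[i]) * (1 - P[j])
            ok = np.isfinite(m_ij)
            pair_sum[ok] += m_ij[ok]
            pair_cnt[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        M_b = pair_sum / pair_cnt

    betas = {}
    for k, pop in enumerate(pops):
        ok = np.isfinite(M_w[k]) & np.isfinite(M_b)
        num = np.sum(1.0 - M_w[k][ok])
        den = np.sum(1.0 - M_b[ok])
        betas[pop] = 1.0 - num / den if den != 0 else np.nan
    return pd.Series(betas, name="beta_fst").sort_index()


# ---------------------------------------------------------------------------
# AMOVA


def _pairwise_mismatch(panel: GenotypePanel):
    """Expected per-locus allele mismatch between random allele copies.

    ``m[i, j]`` is the mean over jointly genotyped loci of
    ``p_i (1 - p_j) + p_j (1 - p_i)`` with ``p = dosage / 2``; ``u[i]`` the
    per-locus heterozygosity of individual i (mismatch of its own two
    copies).  Missing data are pairwise-deleted.
    """
    g = panel.genotypes.to_numpy()
    mask = ~np.isnan(g)
    p = np.where(mask, g / 2.0, 0.0)
    q = np.where(mask, 1.0 - g / 2.0, 0.0)
    M = mask.astype(float)
    shared = M @ M.T
    cross = p @ q.T + q @ p.T
    with np.errstate(invalid="ignore", divide="ignore"):
        m = cross / shared
    np.fill_diagonal(m, 0.0)
    u = np.nansum(g == 1.0, axis=1) / np.maximum(mask.sum(axis=1), 1)
    return m, u, shared


def _amova_components(m: np.ndarray, u: np.ndarray, groups: np.ndarray):
    """Three-stratum AMOVA variance components from copy-level distances."""
    N = len(u)
    labels = np.unique(groups)
    r = len(labels)
    iu = np.triu_indices(N, k=1)
    ss_total = (u.sum() + 4.0 * m[iu].sum()) / (2.0 * N)
    ss_wi = u.sum() / 2.0
    ss_pop_sum = 0.0
    sizes = []
    for lab in labels:
        idx = np.flatnonzero(groups == lab)
        n_p = len(idx)
        sizes.append(n_p)
        mm = m[np.ix_(idx, idx)]
        ss_pop_sum += (u[idx].sum() + 2.0 * mm.sum()) / (2.0 * n_p)
    ss_ai = ss_pop_sum - ss_wi
    ss_ap = ss_total - ss_pop_sum

    df_ap, df_ai, df_wi = r - 1, N - r, N
    ms_ap = ss_ap / df_ap
    ms_ai = ss_ai / df_ai if df_ai > 0 else np.nan
    ms_wi = ss_wi / df_wi
    sizes = np.asarray(sizes, dtype=float)
    n0 = (2.0 * N - np.sum((2.0 * sizes) ** 2) / (2.0 * N)) / (r - 1.0)
    sigma_c = ms_wi
    sigma_b = (ms_ai - sigma_c) / 2.0
    sigma_a = (ms_ap - sigma_c - 2.0 * sigma_b) / n0
    return {
        "ss": {"among_pops": ss_ap, "among_ind_within": ss_ai, "within_ind": ss_wi},
        "df": {"among_pops": df_ap, "among_ind_within": df_ai, "within_ind": df_wi},
        "sigma": {"among_pops": sigma_a, "among_ind_within": sigma_b, "within_ind": sigma_c},
    }


def amova(panel: GenotypePanel, n_perm: int = 999, seed=None) -> dict:
    """Distance-based AMOVA on allele-dosage vectors.

    Squared distances between allele copies derive from dosages (phase-free;
    see methods note); missing loci are pairwise-deleted.  Returns variance
    components, percentages (summing to 100), Phi-statistics, and a
    permutation p-value for population differentiation obtained by shuffling
    individuals among populations and comparing the among-population
    component.
    """
    if len(panel.pop_names) < 2:
        raise ValueError("need at least two populations")
    if n_perm and n_perm < 99:
        raise ValueError("n_perm must be at least 99 (or 0 to skip)")
    m, u, _ = _pairwise_mismatch(panel)
    groups = panel.populations.to_numpy()
    res = _amova_components(m, u, groups)
    sig = res["sigma"]
    total = sum(sig.values())
    res["percent"] = {k: 100.0 * v / total for k, v in sig.items()}
    res["phi"] = {
        "phi_st": sig["among_pops"] / total,
        "phi_is": sig["among_ind_within"]
        / (sig["among_ind_within"] + sig["within_ind"]),
        "phi_it": (sig["among_pops"] + sig["among_ind_within"]) / total,
    }
    if n_perm:
        rng = np.random.default_rng(seed)
        obs = sig["among_pops"]
        hits = 0
        perm_groups = groups.copy()
        for _ in range(n_perm):
            rng.shuffle(perm_groups)
            s = _amova_components(m, u, perm_groups)["sigma"]["among_pops"]
            if s >= obs:
                hits += 1
        res["p_value"] = (1.0 + hits) / (n_perm + 1.0)
        res["n_perm"] = n_perm
    return res


# ---------------------------------------------------------------------------
# distances


def nei_distance(panel: GenotypePanel) -> pd.DataFrame:
    """Nei (1972) standard genetic distance between populations.

    ``D = -ln( Jxy / sqrt(Jx * Jy) )`` with the J terms summed over loci
    jointly genotyped in both populations before taking the ratio.  ``inf``
    when no alleles are shared.
    """
    stats = _pop_locus_arrays(panel)
    pops = panel.pop_names
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    D = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        na, p_a, _ = stats[pa]
        for pb in pops[i + 1:]:
            nb, p_b, _ = stats[pb]
            ok = (na >= 1) & (nb >= 1)
            if not ok.any():
                raise ValueError(f"no jointly genotyped loci for {pa!r} and {pb!r}")
            pa_, pb_ = p_a[ok], p_b[ok]
            jx = np.sum(pa_**2 + (1 - pa_) ** 2)
            jy = np.sum(pb_**2 + (1 - pb_) ** 2)
            jxy = np.sum(pa_ * pb_ + (1 - pa_) * (1 - pb_))
            if jxy == 0:
                d = np.inf
            else:
                d = -np.log(jxy / np.sqrt(jx * jy))
            D.loc[pa, pb] = D.loc[pb, pa] = d
    return D


def kosman_distance(panel: GenotypePanel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kosman–Leonard inter-individual distance and population-pair means.

    Per locus the distance is the fraction of unshared alleles between the
    two diploid genotypes (0 identical, 0.5 het vs hom, 1 opposite
    homozygotes), i.e. ``|g1 - g2| / 2``; averaged over loci genotyped in
    both individuals.  Pairs with no jointly genotyped locus are NaN.
    """
    g = panel.genotypes.to_numpy()
    inds = panel.individuals
    if len(inds) < 2:
        raise ValueError("need at least two individuals")
    mask = ~np.isnan(g)
    gz = np.where(mask, g, 0.0)
    M = mask.astype(float)
    shared = M @ M.T
    # sum over shared loci of |g_i - g_j| = sum g_i^2 masked terms trick is
    # wrong for L1; do it blockwise instead.
    N = len(inds)
    D = np.full((N, N), np.nan)
    for i in range(N):
        diff = np.abs(gz[i] - gz) / 2.0
        both = mask[i] & mask
        s = np.where(both, diff, 0.0).sum(axis=1)
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            D[i] = np.where(cnt > 0, s / cnt, np.nan)
    np.fill_diagonal(D, 0.0)
    if np.isnan(D).any():
        warnings.warn("individual pairs with no jointly genotyped loci: NaN entries")
    Dm = pd.DataFrame(D, index=inds, columns=inds)

    pops = panel.pop_names
    means = pd.DataFrame(np.nan, index=pops, columns=pops)
    idx = panel.pop_indices()
    for i, pa in enumerate(pops):
        for pb in pops[i:]:
            if pa == pb:
                block = D[np.ix_(idx[pa], idx[pa])]
                vals = block[np.triu_indices(len(idx[pa]), k=1)]
            else:
                vals = D[np.ix_(idx[pa], idx[pb])].ravel()
            mean = float(np.nanmean(vals)) if len(vals) else np.nan
            means.loc[pa, pb] = means.loc[pb, pa] = mean
    return Dm, means


def private_alleles(panel: GenotypePanel) -> pd.Series:
    """Per-population count of loci carrying a population-private allele.

    Allele presence is assessed on non-missing genotypes; each allele of a
    locus can be private to at most one population, and a locus counts at
    most once per population.
    """
    if len(panel.pop_names) < 2:
        raise ValueError("need at least two populations")
    stats = _pop_locus_arrays(panel)
    pops = panel.pop_names
    alt = np.array([np.where(stats[p][0] > 0, stats[p][1] > 0, False) for p in pops])
    ref = np.array([np.where(stats[p][0] > 0, stats[p][1] < 1, False) for p in pops])
    counts = {}
    for k, pop in enumerate(pops):
        alt_private = alt[k] & (alt.sum(axis=0) == 1)
        ref_private = ref[k] & (ref.sum(axis=0) == 1)
        counts[pop] = int(np.sum(alt_private | ref_private))
    return pd.Series(counts, name="private_loci").sort_index()


# ---------------------------------------------------------------------------
# Mantel / isolation by distance


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between WGS84 coordinates."""
    r = 6371.0088
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    s = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    return float(2.0 * r * np.arcsin(np.sqrt(s)))


def geographic_distances(coords: pd.DataFrame, method: str = "haversine") -> pd.DataFrame:
    """Pairwise population distances from lat/lon (km, or planar degrees)."""
    pops = list(coords.index)
    D = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            if method == "haversine":
                d = haversine_km(
                    coords.loc[a, "lat"], coords.loc[a, "lon"],
                    coords.loc[b, "lat"], coords.loc[b, "lon"],
                )
            elif method == "euclidean":
                d = float(
                    np.hypot(
                        coords.loc[a, "lat"] - coords.loc[b, "lat"],
                        coords.loc[a, "lon"] - coords.loc[b, "lon"],
                    )
                )
            else:
                raise ValueError(f"unknown method {method!r}")
            D.loc[a, b] = D.loc[b, a] = d
    return D


def mantel(
    d1: pd.DataFrame | np.ndarray,
    d2: pd.DataFrame | np.ndarray,
    n_perm: int = 10000,
    seed=None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel permutation correlation between two distance matrices.

    Pearson r on the condensed (upper-triangle) vectors; the null permutes
    the row/column order of the second matrix.  One-sided by default.
    """
    A = np.asarray(d1, dtype=float)
    B = np.asarray(d2, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrices must be square and congruent")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least three populations")
    iu = np.triu_indices(n, k=1)
    x = A[iu]

    def corr(mat):
        y = mat[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(B[np.ix_(perm, perm)])
        if alternative == "greater":
            hit = r_p >= r_obs
        elif alternative == "less":
            hit = r_p <= r_obs
        else:
            hit = abs(r_p) >= abs(r_obs)
        hits += bool(hit)
    return r_obs, (1.0 + hits) / (n_perm + 1.0)


def mantel_ibd(
    panel: GenotypePanel,
    n_perm: int = 10000,
    seed=None,
    linearize: bool = True,
    geo_method: str = "haversine",
) -> dict:
    """Isolation-by-distance Mantel test.

    Genetic distance is pairwise Weir–Cockerham F_ST, linearized as
    ``F_ST / (1 - F_ST)``; geographic distance is great-circle km from
    population coordinates (planar option available).
    """
    if panel.coords is None:
        raise ValueError("panel has no population coordinates")
    if len(panel.pop_names) < 4:
        raise ValueError("need at least four populations for a meaningful test")
    fst, _ = pairwise_fst(panel, n_boot=0)
    gen = fst / (1.0 - fst) if linearize else fst.copy()
    geo = geographic_distances(panel.coords.loc[gen.index], geo_method)
    r, p = mantel(geo, gen, n_perm=n_perm, seed=seed)
    return {"r": r, "p_value": p, "n_perm": n_perm,
            "genetic": gen, "geographic": geo}


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame  # individuals x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray = field(repr=False, default=None)


def genotype_pca(panel: GenotypePanel, n_components: int = 10) -> PCAResult:
    """PCA of the mean-imputed, column-centered dosage matrix."""
    g = panel.genotypes.to_numpy().copy()
    if g.shape[0] < 3:
        raise ValueError("need at least three individuals")
    col_mean = np.nanmean(g, axis=0)
    dead = ~np.isfinite(col_mean)
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} all-missing loci")
        g = g[:, ~dead]
        col_mean = col_mean[~dead]
    inds = np.where(np.isnan(g))
    g[inds] = col_mean[inds[1]]
    X = g - g.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=panel.individuals,
        columns=[f"PC{i+1}" for i in range(k)],
    )
    return PCAResult(scores, ratio[:k], vt[:k])
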