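"""Differential transcript-end analysis: WT vs RNase-deficient strains.

RNase E ends and exoribonuclease trimming start/stop sites are positions
whose 5' or 3' end counts change when the corresponding enzyme is removed.
The machinery is the standard count-based differential stack:

* per-library normalization by the trimmed mean of M-values (TMM);
* an exact negative-binomial double-tail test on library-size-equalized
  counts (a Poisson/binomial conditional test when the dispersion is zero);
* Benjamini-Hochberg FDR control across tested rows;
* the study-specific end-proportion filters (ends/coverage >= 2% in the
  enriched strain and >= 3-fold the proportion in the other strain);
* greedy 5-nt window clustering keeping the position with the highest end
  proportion in the reference strain.

Mutant strains with a single library are tested against a fixed dispersion
(default biological CV 0.2, i.e. dispersion 0.04), the usual conservative
choice when replication is absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_profiles import EndProfile, STRANDS
from .rpph_caller import ProcessedSite

logger = logging.getLogger("srps")


@dataclass
class Thresholds:
    """The [thresholds] configuration block with the study's defaults."""

    cpm_min: float = 3.0
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    prop_min: float = 0.02
    prop_ratio_min: float = 3.0
    cluster_window: int = 5
    fixed_bcv: float = 0.2
    rne5_overlap_tol: int = 0

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        section = cfg.get("thresholds", cfg)
        known = {k: v for k, v in section.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass(frozen=True)
class RneEnd:
    contig: str
    strand: str
    pos: int
    end_type: str          # "five_prime" | "three_prime"
    log2fc: float
    fdr: float
    prop_ref: float
    prop_mut: float


@dataclass(frozen=True)
class ExoSite:
    enzyme: str            # pnp | rnb | rnr
    site_class: str        # stop3 | start3 | start5
    contig: str
    strand: str
    pos: int
    log2fc: float
    fdr: float
    prop_wt: float
    prop_mut: float


ENZYME_STRAINS = {"pnp": "pnp_del", "rnb": "rnb_del", "rnr": "rnr_del"}


# ---------------------------------------------------------------------------
# End-count matrix
# ---------------------------------------------------------------------------

def build_end_count_matrix(profiles: Mapping[str, EndProfile]
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble per-position 5'/3' end counts across libraries.

    Rows are (contig, strand, pos, end_type) for every position where any
    library records an end; columns are library names.  Library sizes are the
    total fragment counts.
    """
    rows: dict[tuple[str, str, int, str], np.ndarray] = {}
    names = list(profiles)
    sizes = pd.Series({name: prof.total_fragments() for name, prof in profiles.items()},
                      dtype=float)
    keysets: dict[str, set] = {}
    for name, prof in profiles.items():
        for contig in prof.tracks:
            for strand in STRANDS:
                for end_type, arr in (("5p", prof.n5(contig, strand)),
                                      ("3p", prof.n3(contig, strand))):
                    for p in np.flatnonzero(arr):
                        key = (contig, strand, int(p), end_type)
                        if key not in rows:
                            rows[key] = np.zeros(len(names), dtype=np.int64)
                        rows[key][names.index(name)] = int(arr[p])
    if not rows:
        raise ValueError("no end counts in any library")
    index = pd.MultiIndex.from_tuples(rows.keys(),
                                      names=["contig", "strand", "pos", "end_type"])
    mat = pd.DataFrame(np.vstack(list(rows.values())), index=index, columns=names)
    return mat.sort_index(), sizes


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(counts: pd.DataFrame | np.ndarray,
                lib_sizes: Sequence[float] | None = None,
                m_trim: float = 0.30,
                a_trim: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    The reference library is the one whose upper-quartile count rate is
    closest to the mean upper-quartile rate; each library's factor is the
    precision-weighted trimmed mean of per-row M values against the
    reference, trimming 30% of M values and 5% of A values from each tail.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("TMM requires a 2-D matrix with >= 2 libraries")
    if lib_sizes is None:
        n = y.sum(axis=0)
    else:
        n = np.asarray(lib_sizes, dtype=float)
    if np.any(n <= 0):
        bad = int(np.flatnonzero(n <= 0)[0])
        raise ValueError(f"library {bad} has zero total count")

    q75 = np.array([np.quantile(y[:, j] / n[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    log_factors = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(y[:, j], y[:, ref], n[j], n[ref],
                                   m_trim, a_trim)
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              m_trim: float, a_trim: float) -> float:
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M; weights are its inverse
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:     # identical composition: factor 1
        return 0.0
    n = m.size
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = sps.rankdata(m)
    rank_a = sps.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


# ---------------------------------------------------------------------------
# Exact count test
# ---------------------------------------------------------------------------

def estimate_common_dispersion(counts: pd.DataFrame | np.ndarray,
                               lib_sizes: Sequence[float],
                               factors: Sequence[float] | None = None) -> float:
    """Moment estimator of a common NB dispersion on normalized counts.

    For each row, the normalized counts y_ij ~ NB(mu_i, phi) satisfy
    Var = mu + phi mu^2; phi is estimated by pooling (s^2 - mu)/mu^2 across
    rows with positive means, floored at 0.
    """
    y = np.asarray(counts, dtype=float)
    n = np.asarray(lib_sizes, dtype=float)
    f = np.ones_like(n) if factors is None else np.asarray(factors, dtype=float)
    eff = n * f
    scaled = y * (eff.mean() / eff)[np.newaxis, :]
    mu = scaled.mean(axis=1)
    ok = mu > 0
    if not ok.any():
        return 0.0
    var = scaled.var(axis=1, ddof=1)
    num = np.sum(var[ok] - mu[ok])
    den = np.sum(mu[ok] ** 2)
    return float(max(num / den, 0.0)) if den > 0 else 0.0


def _nb_pmf_vector(t: int, n_libs: float, mu: float, dispersion: float,
                   frac: float) -> np.ndarray:
    """log-pmf of Y1 over 0..t where Y1 ~ sum of n1 NB(mu, phi) libraries and
    Y2 = t - Y1 ~ sum of n2 such libraries; `frac` = n1/(n1+n2)."""
    ks = np.arange(t + 1)
    if dispersion <= 0:
        # Poisson limit: conditional on the total, Y1 ~ Binomial(t, frac)
        return sps.binom.logpmf(ks, t, frac)
    n1 = n_libs * frac
    n2 = n_libs - n1
    # sum of m iid NB(mu, phi) is NB(m*mu, phi/m)
    r1, r2 = n1 / dispersion, n2 / dispersion
    p1 = r1 / (r1 + n1 * mu)
    p2 = r2 / (r2 + n2 * mu)
    lp = sps.nbinom.logpmf(ks, r1, p1) + sps.nbinom.logpmf(t - ks, r2, p2)
    return lp


def _double_tail_p(t: int, s1: int, n1: int, n2: int, mu: float,
                   dispersion: float) -> float:
    """Exact double-tail p-value: total probability of outcomes no more
    likely than the observed split (s1, t - s1)."""
    if t == 0:
        return 1.0
    lp = _nb_pmf_vector(t, n1 + n2, mu, dispersion, n1 / (n1 + n2))
    lp -= _logsumexp(lp)   # condition on the observed total
    p_obs = lp[s1]
    mask = lp <= p_obs + 1e-10
    return float(min(np.exp(_logsumexp(lp[mask])), 1.0))


def _logsumexp(x: np.ndarray) -> float:
    from scipy.special import logsumexp

    return float(logsumexp(x))


def count_test(counts: pd.DataFrame,
               group_labels: Sequence[str],
               lib_sizes: Sequence[float] | None = None,
               dispersion: float | str = "estimate",
               prior_count: float = 0.5,
               factors: Sequence[float] | None = None) -> pd.DataFrame:
    """Two-group exact test for differential end counts.

    Counts are scaled to equalized effective library sizes (TMM factor x
    library size); group sums are compared with an exact NB double-tail test
    (binomial when the dispersion is zero).  ``dispersion`` is either
    ``"estimate"`` (moment estimator; requires >= 2 replicates in some group)
    or a fixed non-negative value.  Returns log2FC (group1 vs group2, with
    ``prior_count`` damping), p-values and BH FDR.
    """
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    g1 = labels == groups[0]
    g2 = labels == groups[1]
    n1, n2 = int(g1.sum()), int(g2.sum())

    y = counts.values.astype(float)
    if lib_sizes is None:
        sizes = y.sum(axis=0)
    else:
        sizes = np.asarray(lib_sizes, dtype=float)
    if factors is None:
        factors = tmm_factors(y, sizes) if y.shape[0] >= 2 else np.ones(y.shape[1])
    eff = sizes * np.asarray(factors, dtype=float)
    target = float(np.exp(np.mean(np.log(eff))))
    scaled = y * (target / eff)[np.newaxis, :]

    if isinstance(dispersion, str):
        if dispersion != "estimate":
            raise ValueError(f"unknown dispersion mode {dispersion!r}")
        if max(n1, n2) < 2:
            raise ValueError("dispersion='estimate' needs >= 2 replicates in "
                             "some group; pass a fixed value instead")
        phi = estimate_common_dispersion(y, sizes, factors)
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValueError("fixed dispersion must be >= 0")

    s1 = np.rint(scaled[:, g1].sum(axis=1)).astype(np.int64)
    s2 = np.rint(scaled[:, g2].sum(axis=1)).astype(np.int64)
    mean1 = scaled[:, g1].mean(axis=1)
    mean2 = scaled[:, g2].mean(axis=1)
    log2fc = np.log2((mean1 + prior_count) / (mean2 + prior_count))

    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        t = int(s1[i] + s2[i])
        mu = t / (n1 + n2) if t else 0.0
        pvals[i] = _double_tail_p(t, int(s1[i]), n1, n2, mu, phi)
    fdr = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals

    return pd.DataFrame({
        "log2fc": log2fc,
        "pvalue": pvals,
        "fdr": fdr,
        "mean_group1": mean1,
        "mean_group2": mean2,
    }, index=counts.index)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Proportions and filters
# ---------------------------------------------------------------------------

def _pooled_proportions(index: pd.MultiIndex,
                        profiles: Mapping[str, EndProfile]) -> np.ndarray:
    """Ends/coverage at each (contig, strand, pos, end_type), pooled across
    the given libraries; capped at 1, zero where coverage is zero."""
    props = np.zeros(len(index))
    cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for i, (contig, strand, pos, end_type) in enumerate(index):
        key = (contig, strand)
        if key not in cache:
            n5 = sum(p.n5(contig, strand).astype(np.int64) for p in profiles.values())
            n3 = sum(p.n3(contig, strand).astype(np.int64) for p in profiles.values())
            cov = sum(p.cov(contig, strand).astype(np.int64) for p in profiles.values())
            cache[key] = (n5, n3, cov)
        n5, n3, cov = cache[key]
        ends = n5[pos] if end_type == "5p" else n3[pos]
        props[i] = min(ends / cov[pos], 1.0) if cov[pos] > 0 else 0.0
    return props


def _cpm_filter(counts: pd.DataFrame, sizes: pd.Series,
                group_labels: Sequence[str], cpm_min: float) -> np.ndarray:
    """Keep rows with CPM >= cpm_min in every replicate of at least one group."""
    cpm = counts.values / sizes.values[np.newaxis, :] * 1e6
    labels = np.asarray(group_labels)
    keep = np.zeros(len(counts), dtype=bool)
    for g in pd.unique(labels):
        keep |= (cpm[:, labels == g] >= cpm_min).all(axis=1)
    return keep


def cluster_positions(rows: pd.DataFrame,
                      window: int = 5,
                      prop_col: str = "prop_ref") -> pd.DataFrame:
    """Greedy left-to-right 5-nt window clustering of called positions.

    Within each (contig, strand, end_type), whenever two kept positions fall
    within ``window`` nt, only the one with the higher reference-strain end
    proportion survives (ties toward the 5'-most position).
    """
    if rows.empty:
        return rows
    kept_parts = []
    df = rows.reset_index() if isinstance(rows.index, pd.MultiIndex) else rows.copy()
    group_cols = [c for c in ("contig", "strand", "end_type") if c in df.columns]
    for _, grp in df.groupby(group_cols, sort=False):
        strand = grp["strand"].iloc[0] if "strand" in grp else "+"
        grp = grp.sort_values("pos")
        kept: list[pd.Series] = []
        for _, row in grp.iterrows():
            if kept and row["pos"] - kept[-1]["pos"] <= window - 1:
                prev = kept[-1]
                better = row[prop_col] > prev[prop_col] or (
                    row[prop_col] == prev[prop_col] and strand == "-")
                if better:
                    kept[-1] = row
            else:
                kept.append(row)
        kept_parts.append(pd.DataFrame(kept))
    return pd.concat(kept_parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Site callers
# ---------------------------------------------------------------------------

def call_rne_ends(wt_profiles: Mapping[str, EndProfile],
                  mut_profiles: Mapping[str, EndProfile],
                  other_processed: Iterable[ProcessedSite],
                  thresholds: Thresholds | None = None,
                  dispersion: float | str = "estimate") -> list[RneEnd]:
    """RNase E 5'/3' end calling: WT vs the temperature-sensitive rne strain.

    Rows passing the CPM filter are tested (WT vs mutant); WT-enriched rows
    (log2FC >= 1, FDR < 0.05, WT end proportion >= 2% and >= 3x the mutant's)
    are kept.  5' rows must additionally coincide with an ``other_processed``
    monophosphate site from the processed-fraction caller.  Survivors are
    window-clustered on the WT proportion.
    """
    thr = thresholds or Thresholds()
    profiles = {**wt_profiles, **mut_profiles}
    counts, sizes = build_end_count_matrix(profiles)
    labels = ["WT"] * len(wt_profiles) + ["mut"] * len(mut_profiles)
    keep = _cpm_filter(counts, sizes, labels, thr.cpm_min)
    counts = counts.loc[keep]
    if counts.empty:
        return []
    res = count_test(counts, labels, sizes.values, dispersion=dispersion)
    res["prop_ref"] = _pooled_proportions(counts.index, wt_profiles)
    res["prop_mut"] = _pooled_proportions(counts.index, mut_profiles)

    called = res[(res.log2fc >= thr.lfc_min)
                 & (res.fdr < thr.fdr_max)
                 & (res.prop_ref >= thr.prop_min)
                 & (res.prop_ref >= thr.prop_ratio_min * res.prop_mut)]

    op_positions = {(s.contig, s.strand): [] for s in other_processed}
    for s in other_processed:
        op_positions[(s.contig, s.strand)].append(s.pos)

    def overlaps_other(contig, strand, pos) -> bool:
        arr = op_positions.get((contig, strand))
        if not arr:
            return False
        return any(abs(pos - q) <= thr.rne5_overlap_tol for q in arr)

    called = called.reset_index()
    is5 = (called.end_type == "5p").values
    five = called[is5]
    if len(five):
        ok5 = five.apply(lambda r: overlaps_other(r.contig, r.strand, r.pos), axis=1)
        five = five[ok5.values]
    called = pd.concat([five, called[~is5]], ignore_index=True)
    called = cluster_positions(called, window=thr.cluster_window)

    out = []
    for _, r in called.iterrows():
        out.append(RneEnd(r.contig, r.strand, int(r.pos),
                          "five_prime" if r.end_type == "5p" else "three_prime",
                          float(r.log2fc), float(r.fdr),
                          float(r.prop_ref), float(r.prop_mut)))
    return sorted(out, key=lambda e: (e.contig, e.strand, e.pos, e.end_type))


def call_exo_sites(wt_profiles: Mapping[str, EndProfile],
                   mut_profile: Mapping[str, EndProfile],
                   enzyme: str,
                   thresholds: Thresholds | None = None,
                   dispersion: float | None = None) -> list[ExoSite]:
    """Exoribonuclease trimming site calling: WT vs one knockout library.

    WT-enriched 3' rows are trimming stops (``stop3``); mutant-enriched 3'
    and 5' rows are trimming starts (``start3``) and fully-degraded-fragment
    5' ends (``start5``).  The knockout is a single library, so the exact
    test runs at the fixed dispersion BCV^2 (default 0.2^2 = 0.04).  Each
    class is window-clustered on the proportion in its own reference strain.
    """
    if enzyme not in ENZYME_STRAINS:
        raise ValueError(f"unknown enzyme {enzyme!r}; expected one of "
                         f"{sorted(ENZYME_STRAINS)}")
    thr = thresholds or Thresholds()
    if dispersion is None:
        dispersion = thr.fixed_bcv ** 2
    profiles = {**wt_profiles, **mut_profile}
    counts, sizes = build_end_count_matrix(profiles)
    labels = ["WT"] * len(wt_profiles) + ["mut"] * len(mut_profile)
    keep = _cpm_filter(counts, sizes, labels, thr.cpm_min)
    counts = counts.loc[keep]
    if counts.empty:
        return []
    res = count_test(counts, labels, sizes.values, dispersion=dispersion)
    res["prop_wt"] = _pooled_proportions(counts.index, wt_profiles)
    res["prop_mut"] = _pooled_proportions(counts.index, mut_profile)
    res = res.reset_index()

    sig = res.fdr < thr.fdr_max
    wt_up = sig & (res.log2fc >= thr.lfc_min) \
        & (res.prop_wt >= thr.prop_min) \
        & (res.prop_wt >= thr.prop_ratio_min * res.prop_mut)
    mut_up = sig & (res.log2fc <= -thr.lfc_min) \
        & (res.prop_mut >= thr.prop_min) \
        & (res.prop_mut >= thr.prop_ratio_min * res.prop_wt)

    out: list[ExoSite] = []
    class_defs = [
        ("stop3", wt_up & (res.end_type == "3p"), "prop_wt"),
        ("start3", mut_up & (res.end_type == "3p"), "prop_mut"),
        ("start5", mut_up & (res.end_type == "5p"), "prop_mut"),
    ]
    for cls, mask, ref_col in class_defs:
        sub = res[mask].copy()
        if sub.empty:
            continue
        sub["prop_ref"] = sub[ref_col]
        sub = cluster_positions(sub, window=thr.cluster_window)
        for _, r in sub.iterrows():
            out.append(ExoSite(enzyme, cls, r.contig, r.strand, int(r.pos),
                               float(r.log2fc), float(r.fdr),
                               float(r.prop_wt), float(r.prop_mut)))
    return sorted(out, key=lambda e: (e.site_class, e.contig, e.strand, e.pos))
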