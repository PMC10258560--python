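"""Gene-level differential insertion enrichment between two conditions.

Molecules are aggregated per gene (a molecule counts for a gene iff its TA
position lies within the gene span), low-count genes are removed by a
combined-count threshold (default 128 across the two conditions), and each
remaining gene is tested with a two-sided negative-binomial exact test
conditioned on the gene's total count, with a common dispersion estimated
across genes by the method of moments.  As the dispersion goes to zero the
conditional law degenerates to a binomial — the closed-form limit used as a
verification oracle.  P-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .refdata import GeneFeature

DEFAULT_COUNT_THRESHOLD = 128  # combined start+end molecule count per gene
DISPERSION_FLOOR = 0.01


def count_per_gene(
    spectrum,
    features: Sequence[GeneFeature],
    include_intergenic: bool = False,
) -> pd.Series:
    """Molecule count per gene from an insertion spectrum (strand-collapsed).

    A molecule contributes to a gene iff its (snapped) TA position lies in
    [start, end].  With ``include_intergenic``, molecules falling between
    annotated genes are aggregated under per-interval pseudo-features named
    ``intergenic_<n>``.
    """
    sites = spectrum.site_counts()
    positions = np.array(sorted(pos for (_, pos) in sites), dtype=np.int64)
    weights = np.array([sites[k] for k in sorted(sites)], dtype=np.int64)
    csum = np.concatenate([[0], np.cumsum(weights)])
    out: dict[str, int] = {}
    for f in sorted(features, key=lambda f: f.start):
        lo = int(np.searchsorted(positions, f.start, side="left"))
        hi = int(np.searchsorted(positions, f.end, side="right"))
        out[f.gene_id] = int(csum[hi] - csum[lo])
    if include_intergenic:
        feats = sorted(features, key=lambda f: f.start)
        edges = [0] + [f.end for f in feats]
        nexts = [f.start for f in feats] + [np.iinfo(np.int64).max]
        for i, (left, right) in enumerate(zip(edges, nexts)):
            if right - left <= 1:
                continue
            lo = int(np.searchsorted(positions, left + 1, side="left"))
            hi = int(np.searchsorted(positions, right - 1, side="right"))
            n = int(csum[hi] - csum[lo])
            if n:
                out[f"intergenic_{i:04d}"] = n
    return pd.Series(out, dtype=np.int64)


def build_count_table(
    spectrum_start, spectrum_end, features: Sequence[GeneFeature]
) -> pd.DataFrame:
    """Two-condition gene count table; library sizes stored in ``df.attrs``."""
    tab = pd.DataFrame(
        {
            "start": count_per_gene(spectrum_start, features),
            "end": count_per_gene(spectrum_end, features),
        }
    ).fillna(0).astype(np.int64)
    tab.attrs["library_sizes"] = {
        "start": spectrum_start.total_mapped,
        "end": spectrum_end.total_mapped,
    }
    return tab


def filter_low_count(table: pd.DataFrame, t: int = DEFAULT_COUNT_THRESHOLD) -> pd.DataFrame:
    """Keep genes whose summed count across the two conditions is >= t."""
    if table.shape[1] < 2:
        raise ValidationError("filter_low_count requires two condition columns")
    out = table[table.sum(axis=1) >= t].copy()
    out.attrs = dict(table.attrs)
    return out


def estimate_dispersion(
    table: pd.DataFrame, library_sizes: Mapping[str, int] | None = None
) -> float:
    """Common NB dispersion across genes by the method of moments, floored at 0.01.

    Counts are rescaled to the mean library size; for each gene the
    two-sample moment estimate (s^2 - mu) / mu^2 is formed and averaged
    across genes with positive mean.
    """
    libs = library_sizes or table.attrs.get("library_sizes")
    if not libs:
        raise ValidationError("library sizes required for dispersion estimation")
    sizes = np.array([libs[c] for c in table.columns], dtype=float)
    y = table.to_numpy(dtype=float) * (sizes.mean() / sizes)
    mu = y.mean(axis=1)
    s2 = y.var(axis=1, ddof=1)
    ok = mu > 0
    if not ok.any():
        return DISPERSION_FLOOR
    phi = (s2[ok] - mu[ok]) / mu[ok] ** 2
    return float(max(DISPERSION_FLOOR, phi.mean()))


def nb_test(
    start_count: int,
    end_count: int,
    start_libsize: float,
    end_libsize: float,
    dispersion_estimate: float,
) -> tuple[float, float]:
    """Two-sided NB exact test of one gene's end vs start counts.

    Returns (log2 fold change, p).  The fold change uses library-size
    normalized counts with a 0.5 pseudocount per condition.  Under the null
    of a common normalized mean, the pair (a, n-a) conditioned on the total
    n has mass proportional to NB(a; mu1, phi) * NB(n-a; mu2, phi); the
    two-sided p sums the mass of all outcomes no more probable than the
    observed one.  With phi -> 0 this is the exact binomial test.
    """
    if start_libsize <= 0 or end_libsize <= 0:
        raise ValidationError("library sizes must be positive")
    a, b = int(start_count), int(end_count)
    log2fc = float(
        np.log2(((b + 0.5) / end_libsize) / ((a + 0.5) / start_libsize))
    )
    n = a + b
    if n == 0:
        return log2fc, 1.0
    phi = max(float(dispersion_estimate), 0.0)
    m = n / (start_libsize + end_libsize)  # null mean per unit of library size
    mu1, mu2 = m * start_libsize, m * end_libsize
    k = np.arange(n + 1)
    if phi < 1e-8:
        # Poisson limit: conditional law is Binomial(n, mu2/(mu1+mu2))
        logw = sstats.binom.logpmf(n - k, n, mu2 / (mu1 + mu2))
    else:
        r = 1.0 / phi
        logw = sstats.nbinom.logpmf(k, r, r / (r + mu1)) + sstats.nbinom.logpmf(
            n - k, r, r / (r + mu2)
        )
    logw = logw - logsumexp(logw)
    obs = logw[a]
    p = float(np.exp(logsumexp(logw[logw <= obs + 1e-10])))
    return log2fc, min(p, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_enrichment(
    table: pd.DataFrame,
    library_sizes: Mapping[str, int] | None = None,
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Filter, test and BH-adjust a two-condition gene count table.

    Returns a frame indexed by gene_id with columns count_start, count_end,
    log2FC, p, q.  Normalization metadata (library sizes, dispersion) is
    recorded in ``df.attrs``.
    """
    libs = library_sizes or table.attrs.get("library_sizes")
    if not libs:
        raise ValidationError("library sizes required")
    filtered = filter_low_count(table, count_threshold)
    if dispersion is None:
        dispersion = estimate_dispersion(filtered, libs)
    cols = list(filtered.columns)
    s_col, e_col = cols[0], cols[1]
    rows = []
    for gid, row in filtered.iterrows():
        lfc, p = nb_test(row[s_col], row[e_col], libs[s_col], libs[e_col], dispersion)
        rows.append((gid, int(row[s_col]), int(row[e_col]), lfc, p))
    out = pd.DataFrame(
        rows, columns=["gene_id", "count_start", "count_end", "log2FC", "p"]
    ).set_index("gene_id")
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out.attrs["library_sizes"] = dict(libs)
    out.attrs["dispersion"] = float(dispersion)
    out.attrs["normalization"] = "library_size"
    return out
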