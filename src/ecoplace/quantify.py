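"""Cross-sample normalization and abundance summaries.

Raw per-clade placement counts are made comparable across metagenomes by
a per-sample factor anchored to one reference sample:

    f_s = G_ref / G_s              (G = good-quality read total)
    normalized = raw * f_s / L_g * 100

with ``L_g`` the marker gene length (reference alignment columns).  Since
all reads have the same length, length normalization only matters when
comparing *between* genes (e.g. the prd/rpoB ratio); a switch to set
``L_g = 1`` is provided.

Derived summaries: ecotype proportions (fractions of the focal clade,
e.g. of all SAR11), percent of the prokaryotic community, and the
prd/rpoB ratio, interpreted as the fraction of the focal clade carrying
proteorhodopsin.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd


def normalization_factors(good_read_totals: Mapping[str, int],
                          reference_sample: str) -> dict[str, float]:
    """Per-sample factors f_s = G_ref / G_s (reference sample -> 1)."""
    if reference_sample not in good_read_totals:
        raise KeyError(f"reference sample {reference_sample!r} not in totals")
    g_ref = good_read_totals[reference_sample]
    out = {}
    for sample, g in good_read_totals.items():
        if g <= 0:
            raise ValueError(f"sample {sample!r} has non-positive read total {g}")
        out[sample] = g_ref / g
    return out


def normalize_counts(raw, f_s: float, gene_length: float):
    """normalized = raw * f_s / L_g * 100 (vectorized over raw)."""
    if gene_length <= 0:
        raise ValueError("gene length must be > 0")
    return np.asarray(raw, dtype=float) * f_s / gene_length * 100.0


def ecotype_proportions(normalized_counts: pd.Series) -> pd.Series:
    """Fractions of the focal clade each sub-ecotype makes up.

    Input: normalized counts of mutually exclusive subclades in one
    sample.  Fractions sum to 1; an all-zero sample raises (flag upstream
    with NaN if tolerated).
    """
    counts = pd.Series(normalized_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero sample: ecotype proportions undefined")
    return counts / total


def percent_community(focal_norm: float, total_norm: float) -> float:
    """Percent of the (normalized) total community the focal clade makes up."""
    if total_norm <= 0:
        raise ValueError("total community count must be > 0")
    return 100.0 * focal_norm / total_norm


def prd_rpob_ratio(prd_norm: float, rpob_norm: float) -> float:
    """Proteorhodopsin-to-rpoB normalized-count ratio (carrier fraction).

    Returns NaN (missing) on a zero rpoB denominator, never 0.
    """
    if rpob_norm <= 0:
        return float("nan")
    return prd_norm / rpob_norm


def build_sample_table(raw_counts: Mapping[str, Mapping[str, pd.Series]],
                       good_read_totals: Mapping[str, int],
                       gene_lengths: Mapping[str, int],
                       reference_sample: str | None = None,
                       length_normalize: bool = True,
                       metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format table of raw and normalized per-clade counts.

    Parameters
    ----------
    raw_counts:
        sample id -> gene -> Series of counts indexed by clade path.
    reference_sample:
        Anchor for the normalization factors; defaults to the
        lexicographically first sample (the real study anchors on a fixed
        station/depth sample; make this explicit in configs).
    length_normalize:
        If False, L_g = 1 for every gene (all reads are the same length,
        so within-gene comparisons do not need it).

    Returns columns: sample, gene, clade, raw, norm_factor, normalized
    (joined with ``metadata`` on sample if given).
    """
    if reference_sample is None:
        reference_sample = sorted(good_read_totals)[0]
    factors = normalization_factors(good_read_totals, reference_sample)
    rows = []
    for sample in sorted(raw_counts):
        for gene in sorted(raw_counts[sample]):
            counts = raw_counts[sample][gene]
            lg = gene_lengths[gene] if length_normalize else 1
            norm = normalize_counts(counts.to_numpy(), factors[sample], lg)
            for clade, raw, nval in zip(counts.index, counts.to_numpy(), norm):
                rows.append((sample, gene, clade, int(raw),
                             factors[sample], float(nval)))
    table = pd.DataFrame(rows, columns=["sample", "gene", "clade", "raw",
                                        "norm_factor", "normalized"])
    if metadata is not None:
        table = table.merge(metadata, on="sample", how="left")
    return table


def exclusive_subclade_counts(series: pd.Series, focal: str) -> pd.Series:
    """Terminal-clade counts under a focal prefix, exclusive of children.

    Input is a hierarchy-rolled-up count Series indexed by
    semicolon-joined clade paths; output is indexed by the path segment
    below the focal clade for every path that has no descendant path in
    the series (reads assigned at intermediate ranks are not attributed
    to any sub-ecotype).
    """
    prefix = focal + ";"
    under = {p: c for p, c in series.items() if p.startswith(prefix)}
    terminal = {p: c for p, c in under.items()
                if not any(q.startswith(p + ";") for q in under)}
    out = pd.Series(terminal, dtype=float)
    out.index = [p[len(prefix):] for p in out.index]
    return out


def clade_series(table: pd.DataFrame, gene: str, clade: str) -> pd.Series:
    """Normalized counts of one exact clade path across samples."""
    sub = table[(table["gene"] == gene) & (table["clade"] == clade)]
    return sub.set_index("sample")["normalized"]
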