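"""Synthetic communities with known truth.

Emulates the data the placement pipeline consumes: clade-structured marker
reference packages, depth-structured station compositions, and 150 bp
paired-end nucleotide reads whose clade of origin is recorded.

The generated world mirrors the structure the analysis assumes:

* a surface-vs-deep ecotype turnover in which the summed deep-clade
  fraction follows a logistic in depth with midpoint ``z*`` (the ecotype
  transition depth);
* a low-light photoautotroph ("LLI"-like) psbD profile whose expected
  abundance peaks at ``z*`` (configurable offset);
* clade-dependent proteorhodopsin (prd) carriage — all surface clades
  carry the gene, a configurable fraction of deep clades do — so the
  prd/rpoB ratio decreases across the transition.

Marker read counts scale with each sample's total good-read count, which
is what the downstream per-sample normalization corrects for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import substitution as subst
from .refdata import ReferencePackage, parse_reference_package

OUTGROUP_RANK = "Outgroup"

# aa -> codon list under the standard genetic code (no stops)
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default clade layout for the rpoB (prokaryote) marker
DEFAULT_SURFACE_CLADES = ("Ia.1", "Ia.3", "Ib.2", "IIa.B")
DEFAULT_DEEP_CLADES = ("Ic", "IIb.x")
DEFAULT_BACKGROUND_CLADES = ("BgA", "BgB")
DEFAULT_PSBD_CLADES = ("LLI", "HLII", "Syn", "Euk")


def _clade_taxonomy_path(clade: str, gene: str) -> tuple[str, ...]:
    """Taxonomy path for a synthetic clade name, by marker."""
    if gene == "psbD":
        if clade in ("LLI", "HLII"):
            return ("Phototroph", "Cyano", "Pro", clade)
        if clade == "Syn":
            return ("Phototroph", "Cyano", "Syn")
        return ("Phototroph", "Euk", clade)
    # rpoB / prd: SAR11-style ecotype paths plus background prokaryotes
    if clade.startswith("Bg"):
        return ("Bacteria", "Other", clade)
    group = clade.split(".")[0]  # Ia.1 -> Ia
    if group == clade:
        return ("Bacteria", "SAR11", clade)
    return ("Bacteria", "SAR11", group, clade)


def _root_rank(gene: str) -> str:
    return "Phototroph" if gene == "psbD" else "Bacteria"


@dataclass
class SyntheticRead:
    """One simulated read pair with its generating truth."""

    read_id: str
    mate1: str
    mate2: str
    true_clade: str
    true_gene: str
    true_leaf: str
    frame1: int           # template frame of mate1 (+1 = forward, codon phase 0)
    frame2: int
    sample_id: str


@dataclass
class CommunityTruth:
    """Ground-truth composition of one station's depth profile."""

    station: str
    depths: np.ndarray                       # m, ascending
    clade_fractions: pd.DataFrame            # depths x rpoB clades, rows sum to 1
    surface_clades: tuple[str, ...]
    deep_clades: tuple[str, ...]
    background_clades: tuple[str, ...]
    z_star: float                            # ecotype transition depth, m
    steepness: float                         # 1/m
    prd_carriage: dict[str, bool]
    lli_peak_depth: float                    # m
    psbd_intensity: pd.DataFrame             # depths x psbD clades (relative units)
    good_read_totals: dict[str, int]         # sample id -> good-quality reads
    nominal_total: int

    def sample_id(self, depth: float) -> str:
        return f"{self.station}-{int(round(depth))}m"

    @property
    def sample_ids(self) -> list[str]:
        return [self.sample_id(z) for z in self.depths]

    def deep_fraction(self, depth: float) -> float:
        """Summed deep-clade fraction of the SAR11-like compartment."""
        row = self.clade_fractions.loc[depth]
        sar = row.drop(list(self.background_clades)).sum()
        return float(row[list(self.deep_clades)].sum() / sar)

    def prd_carrier_fraction(self, depth: float) -> float:
        """True fraction of the SAR11-like compartment carrying prd."""
        row = self.clade_fractions.loc[depth]
        sar_clades = list(self.surface_clades) + list(self.deep_clades)
        carriers = [c for c in sar_clades if self.prd_carriage[c]]
        return float(row[carriers].sum() / row[sar_clades].sum())

    def gene_weights(self, gene: str, depth: float) -> pd.Series:
        """Expected per-clade read weight at one depth for a marker gene.

        rpoB: the community fractions themselves; prd: fractions of
        carrier clades only; psbD: the phototroph intensity profile.
        """
        if gene == "psbD":
            return self.psbd_intensity.loc[depth]
        row = self.clade_fractions.loc[depth]
        if gene == "rpoB":
            return row
        if gene == "prd":
            keep = [c for c, carries in self.prd_carriage.items() if carries]
            return row[keep]
        raise ValueError(f"unknown marker gene {gene!r}")

    def truth_table(self) -> pd.DataFrame:
        """Long-format truth TSV content (station, depth, clade, fraction)."""
        rows = []
        for z in self.depths:
            for clade, frac in self.clade_fractions.loc[z].items():
                rows.append((self.station, self.sample_id(z), float(z),
                             clade, float(frac)))
        return pd.DataFrame(rows, columns=["station", "sample", "depth",
                                           "clade", "fraction"])


def _random_clade_subtree(labels: list[str], scale: float,
                          rng: np.random.Generator) -> str:
    """Random binary newick over `labels` with short within-clade branches."""
    nodes = [f"{l}" for l in labels]
    lens = [rng.uniform(0.05, 0.15) * scale for _ in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]}:{lens[i]:.6f},{nodes[j]}:{lens[j]:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        lens = [l for k, l in enumerate(lens) if k not in (i, j)] + \
               [rng.uniform(0.03, 0.10) * scale]
    return nodes[0], lens[0]


def evolve_reference_set(seed: int, n_clades: int = 6, leaves_per_clade: int = 3,
                         depth_scale: float = 0.3, n_columns: int = 300,
                         gene: str = "rpoB",
                         clade_names: tuple[str, ...] | None = None) -> ReferencePackage:
    """Simulate a clade-structured reference package.

    A random rooted topology with ``n_clades`` ingroup clades plus a
    two-leaf outgroup; leaf amino-acid sequences are evolved column-wise
    down the tree under the same equal-rates model the placement
    likelihood uses.  Between-clade stem branches are longer than
    within-clade branches, so within-clade sequence distance is smaller
    than between-clade distance.  Deterministic in ``seed``.
    """
    if n_clades < 2:
        raise ValueError("need at least 2 clades")
    if leaves_per_clade < 1:
        raise ValueError("need at least 1 leaf per clade")
    if depth_scale < 0:
        raise ValueError("depth_scale must be >= 0")
    rng = np.random.default_rng(seed)

    if clade_names is None:
        pool = (DEFAULT_SURFACE_CLADES + DEFAULT_DEEP_CLADES +
                DEFAULT_BACKGROUND_CLADES) if gene != "psbD" else DEFAULT_PSBD_CLADES
        if n_clades > len(pool):
            pool = pool + tuple(f"C{i}" for i in range(n_clades - len(pool)))
        clade_names = pool[:n_clades]
    elif len(clade_names) != n_clades:
        raise ValueError("clade_names length must equal n_clades")

    # ingroup: join clade subtrees by a random binary backbone
    subtrees, stems = [], []
    leaf_clade: dict[str, str] = {}
    for clade in clade_names:
        labels = [f"{clade}_r{i + 1}" for i in range(leaves_per_clade)]
        for l in labels:
            leaf_clade[l] = clade
        if len(labels) == 1:
            sub, stem0 = labels[0], rng.uniform(0.05, 0.15) * depth_scale
        else:
            sub, stem0 = _random_clade_subtree(labels, depth_scale, rng)
        subtrees.append(sub)
        stems.append(stem0 + rng.uniform(0.6, 1.0) * depth_scale)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        merged = f"({subtrees[i]}:{stems[i]:.6f},{subtrees[j]}:{stems[j]:.6f})"
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [merged]
        stems = [s for k, s in enumerate(stems) if k not in (i, j)] + \
                [rng.uniform(0.2, 0.5) * depth_scale]
    og_labels = ["OG_r1", "OG_r2"]
    og_len = rng.uniform(0.05, 0.15) * depth_scale
    og_stem = rng.uniform(0.8, 1.2) * depth_scale
    newick = (f"(({og_labels[0]}:{og_len:.6f},{og_labels[1]}:{og_len:.6f})"
              f":{og_stem:.6f},{subtrees[0]}:{stems[0]:.6f});")

    # evolve sequences down the tree (parse topology first, then simulate)
    import dendropy
    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
    states: dict[int, np.ndarray] = {}
    root_states = subst.stationary_states(n_columns, rng)
    seqs: dict[str, str] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = root_states
        else:
            states[id(node)] = subst.evolve_states(
                states[id(node.parent_node)], node.edge.length, rng)
        if node.is_leaf():
            seqs[node.taxon.label] = subst.decode_aa(states[id(node)])

    root = _root_rank(gene)
    tax_lines = []
    for label in sorted(seqs):
        if label.startswith("OG_"):
            path = (root, OUTGROUP_RANK)
        else:
            path = _clade_taxonomy_path(leaf_clade[label], gene)
        tax_lines.append(f"{label}\t{';'.join(path)}")
    fasta = "".join(f">{l}\n{seqs[l]}\n" for l in sorted(seqs))
    return parse_reference_package(newick, fasta, "\n".join(tax_lines) + "\n",
                                   gene=gene, outgroup=OUTGROUP_RANK)


def logistic_deep_fraction(z: np.ndarray | float, z_star: float,
                           steepness: float) -> np.ndarray | float:
    """Deep-ecotype fraction of the community at depth z (logistic turnover)."""
    from scipy.special import expit
    return expit(steepness * (np.asarray(z, dtype=float) - z_star))


def make_station_truth(seed: int, depths, surface_clades=DEFAULT_SURFACE_CLADES,
                       deep_clades=DEFAULT_DEEP_CLADES, z_star: float = 150.0,
                       steepness: float = 0.05,
                       background_clades=DEFAULT_BACKGROUND_CLADES,
                       background_fraction: float = 0.55,
                       prd_deep_carrier_fraction: float = 0.0,
                       lli_peak_offset: float = 0.0, lli_width: float = 80.0,
                       psbd_clades=DEFAULT_PSBD_CLADES,
                       station: str = "S1", nominal_total: int = 1_000_000,
                       total_sigma: float = 0.2) -> CommunityTruth:
    """Build one station's ground-truth depth structure.

    The summed deep-clade share of the SAR11-like compartment follows
    ``1/(1+exp(-steepness*(z - z_star)))``; surface clades split the
    complement with fixed Dirichlet-drawn weights (constant over depth),
    as do the deep and background clades.  The psbD "LLI" expected
    abundance is a Gaussian bump centred at ``z_star + lli_peak_offset``.
    """
    depths = np.asarray(sorted(float(z) for z in depths))
    if len(depths) < 4:
        raise ValueError("need at least 4 depths per station profile")
    if len(np.unique(depths)) != len(depths):
        raise ValueError("duplicate depths")
    if not (depths[0] <= z_star <= depths[-1]):
        raise ValueError(f"transition depth {z_star} outside sampled range "
                         f"[{depths[0]}, {depths[-1]}]")
    rng = np.random.default_rng(seed)
    surface_clades = tuple(surface_clades)
    deep_clades = tuple(deep_clades)
    background_clades = tuple(background_clades)
    if not background_clades:
        background_fraction = 0.0

    w_surface = rng.dirichlet(np.full(len(surface_clades), 4.0))
    w_deep = rng.dirichlet(np.full(len(deep_clades), 4.0))
    w_bg = (rng.dirichlet(np.full(len(background_clades), 4.0))
            if background_clades else np.zeros(0))

    sar_fraction = 1.0 - background_fraction
    deep_sum = sar_fraction * logistic_deep_fraction(depths, z_star, steepness)
    surf_sum = sar_fraction - deep_sum

    cols = list(surface_clades) + list(deep_clades) + list(background_clades)
    frac = np.concatenate([
        np.outer(surf_sum, w_surface),
        np.outer(deep_sum, w_deep),
        np.outer(np.full(len(depths), background_fraction), w_bg),
    ], axis=1)
    clade_fractions = pd.DataFrame(frac, index=depths, columns=cols)

    carriage = {c: True for c in surface_clades}
    n_deep_carriers = int(round(prd_deep_carrier_fraction * len(deep_clades)))
    deep_order = list(deep_clades)
    for i, c in enumerate(deep_order):
        carriage[c] = i < n_deep_carriers
    for c in background_clades:
        carriage[c] = False

    lli_peak = z_star + lli_peak_offset
    psbd = {}
    for clade in psbd_clades:
        if clade == "LLI":
            psbd[clade] = np.exp(-0.5 * ((depths - lli_peak) / lli_width) ** 2)
        elif clade == "HLII":
            psbd[clade] = 1.2 * np.exp(-depths / 120.0)
        elif clade == "Syn":
            psbd[clade] = 0.6 * np.exp(-depths / 100.0)
        else:  # eukaryotic algae
            psbd[clade] = 0.8 * np.exp(-depths / 90.0)
    psbd_intensity = pd.DataFrame(psbd, index=depths)

    totals = {}
    for z in depths:
        g = int(round(nominal_total * rng.lognormal(0.0, total_sigma)))
        totals[f"{station}-{int(round(z))}m"] = max(g, 1)

    return CommunityTruth(
        station=station, depths=depths, clade_fractions=clade_fractions,
        surface_clades=surface_clades, deep_clades=deep_clades,
        background_clades=background_clades, z_star=float(z_star),
        steepness=float(steepness), prd_carriage=carriage,
        lli_peak_depth=float(lli_peak), psbd_intensity=psbd_intensity,
        good_read_totals=totals, nominal_total=nominal_total)


def _leaves_by_clade(package: ReferencePackage) -> dict[str, list[str]]:
    """Map each synthetic clade name to the reference leaves inside it."""
    out: dict[str, list[str]] = {}
    for label, path in package.taxonomy.paths.items():
        for rank in dict.fromkeys(path):
            out.setdefault(rank, []).append(label)
    return out


def reverse_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Nucleotide sequence coding for ``aa_seq`` with uniform codon choice."""
    parts = []
    for aa in aa_seq:
        codons = _CODONS.get(aa)
        if codons is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        parts.append(codons[rng.integers(len(codons))])
    return "".join(parts)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        # replace with one of the three other bases
        cur = arr[hit]
        choice = rng.integers(0, 3, size=n)
        repl = np.empty(n, dtype=np.uint8)
        for i, (c, k) in enumerate(zip(cur, choice)):
            others = bases[bases != c]
            repl[i] = others[k]
        arr[hit] = repl
    return arr.tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_reads(truth: CommunityTruth, package: ReferencePackage,
                   n_reads: int, mutation_rate: float = 0.0, seed: int = 0,
                   read_length: int = 150, overlap_prob: float = 0.2,
                   max_gap: int = 150) -> tuple[list[SyntheticRead], dict[str, int]]:
    """Simulate paired 150 bp reads for one marker gene across a station.

    Per sample, the read count is ``n_reads`` scaled by the sample's
    good-read total (relative to the nominal total) and by the summed
    per-clade gene weight at that depth; the clade of each read is drawn
    multinomially from those weights.  Templates are random leaves of the
    clade, reverse-translated with uniform codons; mates are sampled as
    forward/reverse 150 bp windows with an inter-mate gap uniform on
    ``[0, max_gap]`` nt (or a negative gap, i.e. overlapping mates, with
    probability ``overlap_prob``); point substitutions are applied at
    ``mutation_rate`` per site.
    """
    if not 0.0 <= mutation_rate < 1.0:
        raise ValueError("mutation_rate must be in [0, 1)")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    gene = package.gene
    clade_leaves = _leaves_by_clade(package)
    # ungapped leaf sequences, reverse-translated once per leaf
    leaf_nt: dict[str, str] = {}
    leaf_aa: dict[str, str] = {}
    for label, seq in package.alignment.sequences.items():
        aa = seq.replace("-", "").replace(".", "")
        leaf_aa[label] = aa
        leaf_nt[label] = reverse_translate(aa, rng)

    reads: list[SyntheticRead] = []
    totals: dict[str, int] = {}
    for z in truth.depths:
        sample = truth.sample_id(z)
        g_s = truth.good_read_totals[sample]
        totals[sample] = g_s
        weights = truth.gene_weights(gene, z)
        wsum = float(weights.sum())
        n_s = int(round(n_reads * wsum * g_s / truth.nominal_total))
        if n_s == 0 or wsum == 0.0:
            continue
        clades = list(weights.index)
        probs = (weights / wsum).to_numpy()
        counts = rng.multinomial(n_s, probs)
        for clade, k in zip(clades, counts):
            candidates = clade_leaves.get(clade)
            if not candidates:
                raise ValueError(f"no reference leaves for clade {clade!r} "
                                 f"on the {gene} tree")
            for _ in range(int(k)):
                leaf = candidates[rng.integers(len(candidates))]
                template = leaf_nt[leaf]
                ln = len(template)
                if rng.random() < overlap_prob:
                    gap = -int(rng.integers(1, read_length))
                else:
                    gap = int(rng.integers(0, max_gap + 1))
                span = 2 * read_length + gap
                if span > ln:
                    gap = max(ln - 2 * read_length, -(read_length - 3))
                    span = 2 * read_length + gap
                start = int(rng.integers(0, max(ln - span, 0) + 1))
                m1 = template[start:start + read_length]
                s2 = start + read_length + gap
                m2_fwd = template[s2:s2 + read_length]
                m1 = _mutate(m1, mutation_rate, rng)
                m2 = revcomp(_mutate(m2_fwd, mutation_rate, rng))
                rid = f"{sample}.{gene}.{len(reads)}"
                # reading-frame offset that realigns the window to codons
                f1 = (3 - start % 3) % 3 + 1
                f2 = (3 - s2 % 3) % 3 + 1
                reads.append(SyntheticRead(
                    read_id=rid, mate1=m1, mate2=m2, true_clade=clade,
                    true_gene=gene, true_leaf=leaf,
                    frame1=f1, frame2=-f2, sample_id=sample))
    return reads, totals


def write_fastq_pair(reads: list[SyntheticRead], path1, path2) -> None:
    """Write mates to a /1,/2 FASTQ file pair (uniform quality)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            q = "I" * len(r.mate1)
            f1.write(f"@{r.read_id}/1\n{r.mate1}\n+\n{q}\n")
            f2.write(f"@{r.read_id}/2\n{r.mate2}\n+\n{'I' * len(r.mate2)}\n")


def read_truth_table(reads: list[SyntheticRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.read_id, r.sample_id, r.true_gene, r.true_clade, r.true_leaf)
         for r in reads],
        columns=["read", "sample", "gene", "clade", "leaf"])
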