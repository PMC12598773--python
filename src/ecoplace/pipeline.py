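"""File-based pipeline orchestration.

One YAML config drives the whole chain:

    place -> quantify -> profiles -> stats

Each stage reads/writes plain TSV (plus jplace for placements) inside the
config's output directory, so stages can be run individually or together
(``run_pipeline``), and reruns with the same config and seed are
byte-identical.  A run manifest records the config hash, seed, library
versions, per-stage record counts and the SHA-256 of every output file.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .placement import (MIN_SCORE, PENDANT_THRESHOLD, PlacementEngine,
                        Recruiter, assign_and_count, filter_pendant,
                        to_jplace)
from .profiles import (ONSET_SUSTAIN, ONSET_THETA, SIMPSON_CUTOFF,
                       StationProfile, landmark_table)
from .quantify import (build_sample_table, exclusive_subclade_counts,
                       prd_rpob_ratio)
from .refdata import ReferencePackage, parse_reference_package
from .stats import pearson_matrix, rda

_FLOAT_FMT = "%.10g"


@dataclass
class SampleSpec:
    """One metagenomic sample: read files plus metadata."""

    sample: str
    station: str
    depth: float
    reads1: str
    reads2: str | None
    good_reads: int
    metadata: dict[str, float] = field(default_factory=dict)


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    genes: dict[str, dict]            # gene -> {tree, alignment, taxonomy, outgroup}
    samples: list[SampleSpec]
    output_dir: str
    seed: int = 0
    reference_sample: str | None = None
    min_score: float = MIN_SCORE
    pendant_threshold: float = PENDANT_THRESHOLD
    simpson_cutoff: float = SIMPSON_CUTOFF
    onset_theta: float = ONSET_THETA
    onset_sustain: int = ONSET_SUSTAIN
    length_normalize: bool = True
    focal_clade: str = "Bacteria;SAR11"
    community_clade: str = "Bacteria"
    deep_clade: str = "IIb.x"
    lli_clade: str = "Phototroph;Cyano;Pro;LLI"
    predictors: tuple[str, ...] = ("depth", "temperature", "oxygen",
                                   "nitrate", "phosphate")
    base_dir: str = "."

    def __post_init__(self) -> None:
        if self.pendant_threshold <= 0 or self.simpson_cutoff < 0:
            raise ValueError("thresholds must be positive")
        names = [s.sample for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample ids in config")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleSpec(
            sample=s["sample"], station=s["station"], depth=float(s["depth"]),
            reads1=s["reads1"], reads2=s.get("reads2"),
            good_reads=int(s["good_reads"]),
            metadata={k: float(v) for k, v in s.items()
                      if k not in ("sample", "station", "depth", "reads1",
                                   "reads2", "good_reads")})
            for s in raw.pop("samples")]
        genes = raw.pop("genes")
        cfg = cls(genes=genes, samples=samples, base_dir=str(path.parent),
                  **{k: v for k, v in raw.items() if v is not None})
        missing = [p for p in cfg._input_paths() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")
        return cfg

    def _resolve(self, p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else Path(self.base_dir) / q)

    def _input_paths(self) -> list[str]:
        out = []
        for spec in self.genes.values():
            out += [self._resolve(spec[k]) for k in ("tree", "alignment",
                                                     "taxonomy")]
        for s in self.samples:
            out.append(self._resolve(s.reads1))
            if s.reads2:
                out.append(self._resolve(s.reads2))
        return out

    @property
    def out(self) -> Path:
        p = Path(self._resolve(self.output_dir))
        p.mkdir(parents=True, exist_ok=True)
        return p

    def config_hash(self) -> str:
        blob = json.dumps({
            "genes": self.genes,
            "samples": [vars(s) for s in self.samples],
            "thresholds": [self.min_score, self.pendant_threshold,
                           self.simpson_cutoff, self.onset_theta,
                           self.onset_sustain, self.length_normalize],
            "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def load_packages(cfg: RunConfig) -> dict[str, ReferencePackage]:
    packages = {}
    for gene, spec in cfg.genes.items():
        packages[gene] = parse_reference_package(
            Path(cfg._resolve(spec["tree"])).read_text(),
            Path(cfg._resolve(spec["alignment"])).read_text(),
            Path(cfg._resolve(spec["taxonomy"])).read_text(),
            gene=gene, outgroup=spec.get("outgroup"))
    return packages


def _read_pairs(cfg: RunConfig, spec: SampleSpec):
    """Yield (read_id, mate1, mate2) from a sample's FASTQ pair."""
    def parse(path):
        fmt = "fasta" if Path(path).suffix in (".fa", ".fasta", ".fna") else "fastq"
        return list(SeqIO.parse(cfg._resolve(path), fmt))

    r1 = parse(spec.reads1)
    r2 = parse(spec.reads2) if spec.reads2 else [None] * len(r1)
    if len(r1) != len(r2):
        raise ValueError(f"sample {spec.sample}: mate files have different "
                         f"read counts ({len(r1)} vs {len(r2)})")
    for a, b in zip(r1, r2):
        rid = a.id.rsplit("/", 1)[0]
        yield rid, str(a.seq), (str(b.seq) if b is not None else None)


def stage_place(cfg: RunConfig,
                packages: dict[str, ReferencePackage] | None = None) -> dict:
    """Recruit, place, filter and count all samples; write counts/funnel/jplace."""
    if packages is None:
        packages = load_packages(cfg)
    recruiter = Recruiter(list(packages.values()))
    engines = {g: PlacementEngine(p) for g, p in packages.items()}
    funnel_rows = []
    count_rows = []
    placements_by_gene: dict[str, list] = {g: [] for g in packages}
    for spec in sorted(cfg.samples, key=lambda s: s.sample):
        stats = dict(sample=spec.sample, reads=0, recruited=0, placed=0,
                     kept=0, removed=0)
        by_gene: dict[str, list] = {}
        for rid, m1, m2 in _read_pairs(cfg, spec):
            stats["reads"] += 1
            query, _reason = recruiter.recruit_pair(rid, m1, m2, cfg.min_score)
            if query is None:
                continue
            stats["recruited"] += 1
            placement = engines[query.gene].place(query, sample_id=spec.sample)
            if placement is None:
                continue
            stats["placed"] += 1
            kept, removed = filter_pendant([placement], cfg.pendant_threshold)
            if removed:
                stats["removed"] += 1
                continue
            stats["kept"] += 1
            by_gene.setdefault(query.gene, []).append(kept[0])
        for gene, pls in sorted(by_gene.items()):
            placements_by_gene[gene].extend(pls)
            counts = assign_and_count(pls, packages[gene].labeling)
            for clade, count in counts.items():
                count_rows.append((spec.sample, gene, clade, int(count)))
        funnel_rows.append(stats)

    counts = pd.DataFrame(count_rows,
                          columns=["sample", "gene", "clade", "count"])
    counts.to_csv(cfg.out / "counts.tsv", sep="\t", index=False)
    funnel = pd.DataFrame(funnel_rows)
    funnel.to_csv(cfg.out / "funnel.tsv", sep="\t", index=False)
    for gene, pls in placements_by_gene.items():
        pls = sorted(pls, key=lambda p: (p.sample_id, p.query_id))
        (cfg.out / f"{gene}.jplace").write_text(to_jplace(packages[gene], pls))
    return {"counts": counts, "funnel": funnel}


def stage_quantify(cfg: RunConfig,
                   packages: dict[str, ReferencePackage] | None = None) -> pd.DataFrame:
    """Normalize counts across samples; write the long-format sample table."""
    if packages is None:
        packages = load_packages(cfg)
    counts = pd.read_csv(cfg.out / "counts.tsv", sep="\t")
    raw: dict[str, dict[str, pd.Series]] = {}
    for (sample, gene), grp in counts.groupby(["sample", "gene"]):
        raw.setdefault(sample, {})[gene] = pd.Series(
            grp["count"].to_numpy(), index=grp["clade"].to_numpy())
    for spec in cfg.samples:      # samples with zero kept reads still appear
        raw.setdefault(spec.sample, {})
    totals = {s.sample: s.good_reads for s in cfg.samples}
    meta = pd.DataFrame([
        dict(sample=s.sample, station=s.station, depth=s.depth, **s.metadata)
        for s in cfg.samples])
    table = build_sample_table(
        raw, totals, {g: p.gene_length for g, p in packages.items()},
        reference_sample=cfg.reference_sample,
        length_normalize=cfg.length_normalize, metadata=meta)
    table.to_csv(cfg.out / "sample_table.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)
    return table


def _station_profiles(cfg: RunConfig, table: pd.DataFrame) -> list[StationProfile]:
    """Per-station profiles from the sample table (needs >= 4 depths each)."""
    focal = cfg.focal_clade

    def norm_of(sub: pd.DataFrame, gene: str, clade: str) -> float:
        sel = sub[(sub["gene"] == gene) & (sub["clade"] == clade)]
        return float(sel["normalized"].iloc[0]) if len(sel) else 0.0

    profiles = []
    for station, sgrp in table.groupby("station"):
        depths = sorted(sgrp["depth"].unique())
        if len(depths) < 4:
            print(f"[profiles] station {station}: only {len(depths)} depths, "
                  "skipped", file=sys.stderr)
            continue
        sub_names: set[str] = set()
        per_sample = {d: sgrp[sgrp["depth"] == d] for d in depths}
        for d in depths:
            s = per_sample[d]
            rpo = s[s["gene"] == "rpoB"].set_index("clade")["normalized"]
            sub_names |= set(exclusive_subclade_counts(rpo, focal).index)
        sub_names = sorted(sub_names)
        rows, ratios, llis = [], [], []
        for d in depths:
            s = per_sample[d]
            rpo = s[s["gene"] == "rpoB"].set_index("clade")["normalized"]
            sub = exclusive_subclade_counts(rpo, focal)
            rows.append({name: float(sub.get(name, 0.0)) for name in sub_names})
            ratios.append(prd_rpob_ratio(norm_of(s, "prd", focal),
                                         norm_of(s, "rpoB", focal)))
            llis.append(norm_of(s, "psbD", cfg.lli_clade))
        profiles.append(StationProfile(
            station=str(station), depths=np.asarray(depths, dtype=float),
            clade_abundance=pd.DataFrame(rows, index=depths),
            prd_rpob=np.array(ratios), lli=np.array(llis)))
    return profiles


def stage_profiles(cfg: RunConfig) -> dict:
    """Depth-profile analytics; writes profiles.tsv and landmarks.tsv."""
    from .quantify import percent_community

    table = pd.read_csv(cfg.out / "sample_table.tsv", sep="\t")
    profiles = _station_profiles(cfg, table)

    pct: dict[tuple, float] = {}
    for (station, depth), s in table.groupby(["station", "depth"]):
        rpo = s[s["gene"] == "rpoB"].set_index("clade")["normalized"]
        focal = float(rpo.get(cfg.focal_clade, 0.0))
        total = float(rpo.get(cfg.community_clade, 0.0))
        pct[(str(station), float(depth))] = (
            percent_community(focal, total) if total > 0 else np.nan)

    rows = []
    for prof in profiles:
        simpson = prof.simpson_series(cfg.simpson_cutoff)
        total = prof.clade_abundance.sum(axis=1)
        for i, z in enumerate(prof.depths):
            row = dict(station=prof.station, depth=z,
                       pct_community=pct.get((prof.station, float(z)), np.nan),
                       simpson_1_minus_D=simpson.iloc[i],
                       prd_rpob_ratio=prof.prd_rpob[i], lli=prof.lli[i])
            for clade in prof.clade_abundance.columns:
                row[f"abund_{clade}"] = prof.clade_abundance.iloc[i][clade]
                row[f"prop_{clade}"] = (
                    prof.clade_abundance.iloc[i][clade] / total.iloc[i]
                    if total.iloc[i] > 0 else np.nan)
            rows.append(row)
    pd.DataFrame(rows).to_csv(cfg.out / "profiles.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    landmarks = landmark_table(profiles, cfg.deep_clade, cfg.onset_theta,
                               cfg.onset_sustain)
    landmarks.to_csv(cfg.out / "landmarks.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
    return {"profiles": profiles, "landmarks": landmarks}


def _stats_table(cfg: RunConfig, table: pd.DataFrame) -> tuple[pd.DataFrame,
                                                               list[str]]:
    """Samples x (ecotype proportions + environmental variables)."""
    rows = []
    clade_cols: set[str] = set()
    for sample, s in table.groupby("sample"):
        rpo = s[s["gene"] == "rpoB"].set_index("clade")["normalized"]
        sub = exclusive_subclade_counts(rpo, cfg.focal_clade)
        row = dict(sample=sample, _has_counts=sub.sum() > 0)
        if sub.sum() > 0:
            for clade, val in (sub / sub.sum()).items():
                row[clade] = val
                clade_cols.add(clade)
        for var in cfg.predictors:
            if var in s.columns:
                row[var] = float(s[var].iloc[0])
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample").sort_index()
    clades = sorted(clade_cols)
    # a clade absent from a sample that did yield counts is a true zero
    if clades:
        has = df.pop("_has_counts").astype(bool)
        df.loc[has, clades] = df.loc[has, clades].fillna(0.0)
    else:
        df = df.drop(columns=["_has_counts"])
    return df, clades


def stage_stats(cfg: RunConfig) -> dict:
    """Correlation matrix and RDA; writes correlations.tsv and rda_*.tsv."""
    table = pd.read_csv(cfg.out / "sample_table.tsv", sep="\t")
    df, clade_cols = _stats_table(cfg, table)
    corr = pearson_matrix(df)
    corr.to_csv(cfg.out / "correlations.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)
    result = {"correlations": corr, "rda": None}
    predictors = [v for v in cfg.predictors if v in df.columns]
    Y = df[clade_cols].dropna()
    X = df.loc[Y.index, predictors]
    if len(Y) >= len(predictors) + 2 and clade_cols:
        res = rda(Y, X)
        summary = pd.DataFrame({
            "quantity": ["constrained_proportion"] +
                        [f"eigenvalue_{i + 1}" for i in range(len(res.eigenvalues))],
            "value": [res.constrained_proportion] + list(res.eigenvalues)})
        summary.to_csv(cfg.out / "rda_summary.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FMT)
        res.site_scores.to_csv(cfg.out / "rda_site_scores.tsv", sep="\t",
                               float_format=_FLOAT_FMT)
        res.response_scores.to_csv(cfg.out / "rda_response_scores.tsv",
                                   sep="\t", float_format=_FLOAT_FMT)
        res.predictor_loadings.to_csv(cfg.out / "rda_predictor_loadings.tsv",
                                      sep="\t", float_format=_FLOAT_FMT)
        result["rda"] = res
    else:
        print("[stats] too few complete samples for RDA, skipped",
              file=sys.stderr)
    return result


def run_pipeline(cfg: RunConfig) -> dict:
    """All stages in order, plus the run manifest.  Returns stage results."""
    packages = load_packages(cfg)
    placed = stage_place(cfg, packages)
    stage_quantify(cfg, packages)
    prof = stage_profiles(cfg)
    stats = stage_stats(cfg)

    funnel = placed["funnel"]
    totals = {c: int(funnel[c].sum())
              for c in ("reads", "recruited", "placed", "kept", "removed")}
    outputs = {}
    for path in sorted(cfg.out.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "config_sha256": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {"ecoplace": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "thresholds": {"min_score": cfg.min_score,
                       "pendant_threshold": cfg.pendant_threshold,
                       "simpson_cutoff": cfg.simpson_cutoff,
                       "onset_theta": cfg.onset_theta,
                       "onset_sustain": cfg.onset_sustain,
                       "length_normalize": cfg.length_normalize,
                       "reference_sample": cfg.reference_sample},
        "stage_counts": totals,
        "outputs": outputs,
    }
    (cfg.out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return {"manifest": manifest, **placed, **prof, **stats}
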