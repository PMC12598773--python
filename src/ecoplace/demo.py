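"""Write a self-contained synthetic demo dataset + config to disk.

Produces everything ``run_pipeline`` needs: reference packages (newick /
FASTA / taxonomy TSV per marker), per-sample paired FASTQ files with all
three markers mixed, depth-dependent environmental metadata, the
generating truth tables, and a ready-to-run ``config.yaml``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .harness import build_world, simulate_station
from .refdata import ReferencePackage
from .synth import OUTGROUP_RANK, make_station_truth, read_truth_table, \
    write_fastq_pair


def environmental_metadata(truth, seed: int) -> pd.DataFrame:
    """Plausible open-ocean metadata profiles for a synthetic station.

    Temperature decays from a warm mixed layer, oxygen declines toward a
    mid-water minimum, nutrients increase with depth (saturating), each
    with small lognormal-ish noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for z in truth.depths:
        rows.append(dict(
            sample=truth.sample_id(z), station=truth.station, depth=float(z),
            temperature=round(3.0 + 25.0 * np.exp(-z / 140.0)
                              + rng.normal(0, 0.3), 3),
            oxygen=round(max(5.0, 235.0 * np.exp(-z / 350.0)
                             + rng.normal(0, 6.0)), 3),
            nitrate=round(max(0.05, 36.0 * z / (z + 250.0)
                              + rng.normal(0, 0.8)), 3),
            phosphate=round(max(0.02, 2.4 * z / (z + 250.0)
                                + rng.normal(0, 0.06)), 3),
        ))
    return pd.DataFrame(rows)


def write_package(pkg: ReferencePackage, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(pkg.tree.newick() + "\n")
    (outdir / "alignment.fasta").write_text(pkg.alignment.to_fasta())
    (outdir / "taxonomy.tsv").write_text(pkg.taxonomy.to_tsv())
    return {"tree": str(outdir / "tree.nwk"),
            "alignment": str(outdir / "alignment.fasta"),
            "taxonomy": str(outdir / "taxonomy.tsv"),
            "outgroup": OUTGROUP_RANK}


def write_demo(outdir, seed: int = 0, n_stations: int = 2, n_depths: int = 8,
               depth_start: float = 25.0, depth_step: float = 50.0,
               n_rpob: int = 150, mutation_rate: float = 0.02) -> Path:
    """Generate a small multi-station dataset; returns the config path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    packages = build_world(int(rng.integers(2**31)))
    gene_specs = {g: write_package(p, outdir / "refpkg" / g)
                  for g, p in packages.items()}

    depths = depth_start + depth_step * np.arange(n_depths)
    z_lo, z_hi = depths[1], depths[-2]
    z_stars = np.linspace(z_lo + 25, z_hi - 75, max(n_stations, 1))
    samples = []
    truth_frames, read_frames = [], []
    (outdir / "reads").mkdir(exist_ok=True)
    for k, z_star in enumerate(z_stars):
        truth = make_station_truth(int(rng.integers(2**31)), depths,
                                   z_star=float(z_star), station=f"S{k + 1}")
        reads, totals = simulate_station(truth, packages, n_rpob=n_rpob,
                                         mutation_rate=mutation_rate,
                                         seed=int(rng.integers(2**31)))
        meta = environmental_metadata(truth, int(rng.integers(2**31)))
        truth_frames.append(truth.truth_table())
        read_frames.append(read_truth_table(reads))
        for z in truth.depths:
            s = truth.sample_id(z)
            sample_reads = [r for r in reads if r.sample_id == s]
            r1 = outdir / "reads" / f"{s}_R1.fastq"
            r2 = outdir / "reads" / f"{s}_R2.fastq"
            write_fastq_pair(sample_reads, r1, r2)
            m = meta[meta["sample"] == s].iloc[0]
            samples.append(dict(
                sample=s, station=truth.station, depth=float(z),
                reads1=str(Path("reads") / r1.name),
                reads2=str(Path("reads") / r2.name),
                good_reads=int(totals[s]),
                temperature=float(m["temperature"]), oxygen=float(m["oxygen"]),
                nitrate=float(m["nitrate"]), phosphate=float(m["phosphate"])))

    pd.concat(truth_frames).to_csv(outdir / "truth_fractions.tsv", sep="\t",
                                   index=False, float_format="%.10g")
    pd.concat(read_frames).to_csv(outdir / "truth_reads.tsv", sep="\t",
                                  index=False)
    config = dict(
        genes={g: {k: str(Path(v).relative_to(outdir)) if k != "outgroup" else v
                   for k, v in spec.items()}
               for g, spec in gene_specs.items()},
        samples=samples,
        output_dir="out",
        seed=seed,
    )
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return cfg_path
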