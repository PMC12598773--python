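"""End-to-end recovery harness on synthetic communities.

Builds a three-marker synthetic world (rpoB for prokaryote ecotypes, prd
for proteorhodopsin carriage, psbD for phototrophs), simulates station
depth profiles with a known ecotype-transition depth z*, pushes the reads
through recruit -> place -> filter -> assign -> normalize, and measures
how well the pipeline recovers the generating truth: per-read clade
assignment, per-depth ecotype proportions, and the three transition
landmarks (prd/rpoB negative-derivative depth, LLI maximum depth, deep
clade onset depth) including their cross-station agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .placement import (MIN_SCORE, PENDANT_THRESHOLD, PlacementEngine,
                        Recruiter, assign_and_count, filter_pendant)
from .profiles import StationProfile, landmark_table
from .quantify import (build_sample_table, exclusive_subclade_counts,
                       prd_rpob_ratio)
from .refdata import ReferencePackage
from .stats import linear_regression
from .synth import (DEFAULT_DEEP_CLADES, DEFAULT_SURFACE_CLADES,
                    CommunityTruth, SyntheticRead, _clade_taxonomy_path,
                    evolve_reference_set, generate_reads, make_station_truth)

#: taxonomy paths of the focal groups in the synthetic world
FOCAL_CLADE = "Bacteria;SAR11"
COMMUNITY_CLADE = "Bacteria"
DEEP_CLADE_NAME = "IIb.x"
LLI_PATH = "Phototroph;Cyano;Pro;LLI"


def build_world(seed: int, n_columns: int = 300,
                leaves_per_clade: int = 3,
                depth_scale: float = 0.3) -> dict[str, ReferencePackage]:
    """Reference packages for the three markers, deterministically from seed."""
    rng = np.random.default_rng(seed)
    sar_clades = DEFAULT_SURFACE_CLADES + DEFAULT_DEEP_CLADES
    packages = {
        "rpoB": evolve_reference_set(
            int(rng.integers(2**31)), n_clades=8,
            leaves_per_clade=leaves_per_clade, depth_scale=depth_scale,
            n_columns=n_columns, gene="rpoB"),
        "prd": evolve_reference_set(
            int(rng.integers(2**31)), n_clades=len(sar_clades),
            leaves_per_clade=leaves_per_clade, depth_scale=depth_scale,
            n_columns=max(60, int(n_columns * 0.8)), gene="prd",
            clade_names=sar_clades),
        "psbD": evolve_reference_set(
            int(rng.integers(2**31)), n_clades=4,
            leaves_per_clade=leaves_per_clade, depth_scale=depth_scale,
            n_columns=max(60, int(n_columns * 0.9)), gene="psbD"),
    }
    return packages


def simulate_station(truth: CommunityTruth, packages: dict[str, ReferencePackage],
                     n_rpob: int, n_psbd: int | None = None,
                     mutation_rate: float = 0.02, seed: int = 0,
                     ) -> tuple[list[SyntheticRead], dict[str, int]]:
    """Reads for all three markers at one station.

    prd read depth is scaled by gene length relative to rpoB so that
    normalized prd/rpoB equals the carrier fraction in expectation (in a
    shotgun library, reads hitting a gene scale with its length).
    """
    rng = np.random.default_rng(seed)
    reads: list[SyntheticRead] = []
    totals: dict[str, int] = {}
    l_rpob = packages["rpoB"].gene_length
    plan = {"rpoB": n_rpob}
    if "prd" in packages:
        plan["prd"] = int(round(n_rpob * packages["prd"].gene_length / l_rpob))
    if "psbD" in packages:
        plan["psbD"] = n_psbd if n_psbd is not None else max(1, n_rpob // 2)
    for gene, n in plan.items():
        r, t = generate_reads(truth, packages[gene], n_reads=n,
                              mutation_rate=mutation_rate,
                              seed=int(rng.integers(2**31)))
        reads.extend(r)
        totals.update(t)
    return reads, totals


@dataclass
class PlacementOutcome:
    """Everything the downstream analysis needs from the placement stage."""

    counts: dict[str, dict[str, pd.Series]]   # sample -> gene -> clade counts
    n_reads: int = 0
    n_recruited: int = 0
    n_placed: int = 0
    n_kept: int = 0
    n_removed: int = 0
    n_true_assignments: int = 0               # kept reads whose label is an
                                              # ancestor-or-equal of the truth
    n_scored_assignments: int = 0
    rejections: dict[str, int] = field(default_factory=dict)

    @property
    def assignment_accuracy(self) -> float:
        if self.n_scored_assignments == 0:
            return float("nan")
        return self.n_true_assignments / self.n_scored_assignments

    @property
    def removed_fraction(self) -> float:
        if self.n_placed == 0:
            return float("nan")
        return self.n_removed / self.n_placed


def run_reads(reads: list[SyntheticRead], packages: dict[str, ReferencePackage],
              min_score: float = MIN_SCORE,
              pendant_threshold: float = PENDANT_THRESHOLD,
              recruiter: Recruiter | None = None,
              engines: dict[str, PlacementEngine] | None = None,
              score_min_columns: int = 0) -> PlacementOutcome:
    """Recruit, place, filter and count a batch of synthetic reads.

    ``score_min_columns``: only queries with at least this many mapped
    columns enter the assignment-accuracy tally (all are still counted).
    """
    if recruiter is None:
        recruiter = Recruiter(list(packages.values()))
    if engines is None:
        engines = {g: PlacementEngine(p) for g, p in packages.items()}
    out = PlacementOutcome(counts={})
    per_sample: dict[str, dict[str, list]] = {}
    for read in reads:
        out.n_reads += 1
        query, reason = recruiter.recruit_pair(read.read_id, read.mate1,
                                               read.mate2, min_score)
        if query is None:
            out.rejections[reason] = out.rejections.get(reason, 0) + 1
            continue
        out.n_recruited += 1
        placement = engines[query.gene].place(query, sample_id=read.sample_id)
        if placement is None:
            out.rejections["unplaceable"] = out.rejections.get("unplaceable", 0) + 1
            continue
        out.n_placed += 1
        kept, removed = filter_pendant([placement], pendant_threshold)
        if removed:
            out.n_removed += 1
            continue
        out.n_kept += 1
        p = kept[0]
        per_sample.setdefault(read.sample_id, {}).setdefault(query.gene,
                                                             []).append(p)
        # truth comparison: assigned path must be a prefix of the true path
        true_path = _clade_taxonomy_path(read.true_clade, read.true_gene)
        if read.true_gene == query.gene and len(query.columns) >= score_min_columns:
            out.n_scored_assignments += 1
            if p.clade == true_path[:len(p.clade)]:
                out.n_true_assignments += 1
    for sample, by_gene in per_sample.items():
        out.counts[sample] = {
            gene: assign_and_count(pls, packages[gene].labeling)
            for gene, pls in by_gene.items()}
    return out


def station_profile_from_counts(truth: CommunityTruth,
                                outcome: PlacementOutcome,
                                packages: dict[str, ReferencePackage],
                                totals: dict[str, int],
                                length_normalize: bool = True) -> StationProfile:
    """Assemble the per-depth analysis series for one simulated station."""
    gene_lengths = {g: p.gene_length for g, p in packages.items()}
    raw = {s: outcome.counts.get(s, {}) for s in truth.sample_ids}
    table = build_sample_table(raw, totals, gene_lengths,
                               reference_sample=sorted(totals)[0],
                               length_normalize=length_normalize)

    def norm(sample: str, gene: str, clade: str) -> float:
        sel = table[(table["sample"] == sample) & (table["gene"] == gene) &
                    (table["clade"] == clade)]
        return float(sel["normalized"].iloc[0]) if len(sel) else 0.0

    clade_rows, ratios, llis = [], [], []
    all_subclades: set[str] = set()
    for s in truth.sample_ids:
        if "rpoB" in raw[s]:
            all_subclades |= set(
                exclusive_subclade_counts(raw[s]["rpoB"], FOCAL_CLADE).index)
    all_subclades = sorted(all_subclades)
    for z in truth.depths:
        s = truth.sample_id(z)
        row = {clade: norm(s, "rpoB", f"{FOCAL_CLADE};{clade}")
               for clade in all_subclades}
        clade_rows.append(row)
        ratios.append(prd_rpob_ratio(norm(s, "prd", FOCAL_CLADE),
                                     norm(s, "rpoB", FOCAL_CLADE)))
        llis.append(norm(s, "psbD", LLI_PATH))
    clade_df = pd.DataFrame(clade_rows, index=truth.depths).fillna(0.0)
    return StationProfile(station=truth.station, depths=truth.depths,
                          clade_abundance=clade_df,
                          prd_rpob=np.array(ratios), lli=np.array(llis))


def estimated_proportions(outcome: PlacementOutcome, truth: CommunityTruth,
                          ) -> pd.DataFrame:
    """Per-depth estimated fractions of the focal clade per sub-ecotype.

    Columns are terminal clade names (matching the generator's naming).
    """
    rows = []
    for z in truth.depths:
        s = truth.sample_id(z)
        counts = outcome.counts.get(s, {}).get("rpoB")
        if counts is None:
            rows.append({})
            continue
        sub = exclusive_subclade_counts(counts, FOCAL_CLADE)
        sub.index = [p.split(";")[-1] for p in sub.index]
        total = sub.sum()
        rows.append({} if total == 0 else (sub / total).to_dict())
    return pd.DataFrame(rows, index=truth.depths).fillna(0.0)


def true_proportions(truth: CommunityTruth) -> pd.DataFrame:
    """Truth fractions of the SAR11-like compartment per sub-ecotype."""
    sar = list(truth.surface_clades) + list(truth.deep_clades)
    sub = truth.clade_fractions[sar]
    return sub.div(sub.sum(axis=1), axis=0)


@dataclass
class ValidationReport:
    """Recovery metrics from one synthetic multi-station run."""

    assignment_accuracy: float
    removed_fraction: float
    proportion_max_abs_error: float
    proportion_sum_error: float
    landmarks: pd.DataFrame          # station, z_star, z_negmax, z_lli, z_onset
    grid_step: float
    landmark_regression_r2: float
    landmark_regression_p: float
    funnel: dict[str, int]

    def landmark_max_offsets(self) -> dict[str, float]:
        """Worst |landmark - z*| per landmark, in grid steps."""
        out = {}
        for col in ("z_negmax", "z_lli", "z_onset"):
            diffs = (self.landmarks[col] - self.landmarks["z_star"]).abs()
            out[col] = float(diffs.max() / self.grid_step)
        return out

    def to_dict(self) -> dict:
        offs = self.landmark_max_offsets()
        return {
            "assignment_accuracy": self.assignment_accuracy,
            "removed_fraction": self.removed_fraction,
            "proportion_max_abs_error": self.proportion_max_abs_error,
            "landmark_negmax_max_offset_steps": offs["z_negmax"],
            "landmark_lli_max_offset_steps": offs["z_lli"],
            "landmark_onset_max_offset_steps": offs["z_onset"],
            "landmark_regression_r2": self.landmark_regression_r2,
            "landmark_regression_p": self.landmark_regression_p,
            "n_stations": int(len(self.landmarks)),
            **{f"funnel_{k}": v for k, v in self.funnel.items()},
        }


def placement_oracle_check(seed: int, n_instances: int = 100,
                           max_leaves: int = 6, max_columns: int = 30,
                           ) -> tuple[float, int]:
    """Compare the engine with the brute-force oracle on random instances.

    Returns (worst |log-likelihood difference|, number of edge-choice
    mismatches) over ``n_instances`` random packages (<= max_leaves
    leaves) and random queries (10..max_columns mapped columns).
    """
    from .bruteforce import place_query_bruteforce
    from .placement import AlignedQuery

    rng = np.random.default_rng(seed)
    worst = 0.0
    mismatches = 0
    done = 0
    while done < n_instances:
        pkg = evolve_reference_set(
            seed=int(rng.integers(2**31)), n_clades=int(rng.integers(2, 4)),
            leaves_per_clade=int(rng.integers(1, 3)),
            depth_scale=float(rng.uniform(0.1, 0.6)), n_columns=max_columns)
        if len(pkg.tree.leaves) > max_leaves:
            continue
        engine = PlacementEngine(pkg)
        ncols = int(rng.integers(10, max_columns + 1))
        cols = np.sort(rng.choice(pkg.gene_length, size=ncols, replace=False))
        res = rng.integers(0, 20, size=ncols)
        q = AlignedQuery(f"oracle{done}", pkg.gene, cols, res, score=100.0)
        p_fast = engine.place(q)
        p_slow = place_query_bruteforce(q, pkg)
        worst = max(worst, abs(p_fast.log_likelihood - p_slow.log_likelihood))
        if p_fast.edge_id != p_slow.edge_id:
            mismatches += 1
        done += 1
    return worst, mismatches


def clade_recovery_check(seed: int, n_reads: int = 2000,
                         mutation_rate: float = 0.02,
                         min_columns: int = 50) -> PlacementOutcome:
    """Single deep-sampled station; accuracy scored on well-covered reads."""
    rng = np.random.default_rng(seed)
    packages = {"rpoB": build_world(int(rng.integers(2**31)))["rpoB"]}
    depths = 25.0 + 50.0 * np.arange(8)
    truth = make_station_truth(int(rng.integers(2**31)), depths, z_star=200.0,
                               background_fraction=0.0)
    # spread the read budget over the profile: n per nominal sample
    reads, _ = generate_reads(truth, packages["rpoB"],
                              n_reads=max(1, n_reads // len(depths)),
                              mutation_rate=mutation_rate,
                              seed=int(rng.integers(2**31)))
    return run_reads(reads, packages, score_min_columns=min_columns)


def proportion_recovery_check(seed: int, n_depths: int = 10,
                              n_reads: int = 2000,
                              mutation_rate: float = 0.02,
                              ) -> tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """One 10-depth station at full read depth; returns (est, truth,
    max |proportion error|, max |row sum - 1|).

    The station is generated without background clades so the whole rpoB
    read budget samples the focal (SAR11-like) compartment.
    """
    rng = np.random.default_rng(seed)
    packages = {"rpoB": build_world(int(rng.integers(2**31)))["rpoB"]}
    depths = 20.0 + 50.0 * np.arange(n_depths)
    truth = make_station_truth(int(rng.integers(2**31)), depths,
                               z_star=float(np.median(depths)),
                               background_fraction=0.0, total_sigma=0.0)
    reads, _ = generate_reads(truth, packages["rpoB"], n_reads=n_reads,
                              mutation_rate=mutation_rate,
                              seed=int(rng.integers(2**31)))
    outcome = run_reads(reads, packages)
    est = estimated_proportions(outcome, truth)
    tru = true_proportions(truth)
    err = (est.reindex(columns=tru.columns, fill_value=0.0) - tru).abs()
    sums = est.sum(axis=1)
    sum_err = float((sums[sums > 0] - 1.0).abs().max())
    return est, tru, float(err.to_numpy().max()), sum_err


def simulate_and_validate(seed: int, n_stations: int = 8,
                          depth_start: float = 25.0, depth_step: float = 50.0,
                          n_depths: int = 13,
                          z_star_range: tuple[float, float] = (100.0, 600.0),
                          n_rpob: int = 700, n_psbd: int | None = None,
                          mutation_rate: float = 0.02,
                          min_score: float = MIN_SCORE,
                          pendant_threshold: float = PENDANT_THRESHOLD,
                          background_fraction: float = 0.55,
                          ) -> ValidationReport:
    """Simulate stations with varying z*, run the pipeline, score recovery."""
    rng = np.random.default_rng(seed)
    packages = build_world(int(rng.integers(2**31)))
    recruiter = Recruiter(list(packages.values()))
    engines = {g: PlacementEngine(p) for g, p in packages.items()}
    depths = depth_start + depth_step * np.arange(n_depths)
    z_stars = (np.linspace(z_star_range[0], z_star_range[1], n_stations)
               if n_stations > 1 else np.array([np.mean(z_star_range)]))

    landmark_rows = []
    max_prop_err = 0.0
    max_sum_err = 0.0
    agg = PlacementOutcome(counts={})
    for k, z_star in enumerate(z_stars):
        truth = make_station_truth(
            int(rng.integers(2**31)), depths, z_star=float(z_star),
            station=f"S{k + 1}", background_fraction=background_fraction)
        reads, totals = simulate_station(
            truth, packages, n_rpob=n_rpob, n_psbd=n_psbd,
            mutation_rate=mutation_rate, seed=int(rng.integers(2**31)))
        outcome = run_reads(reads, packages, min_score, pendant_threshold,
                            recruiter=recruiter, engines=engines)
        for attr in ("n_reads", "n_recruited", "n_placed", "n_kept",
                     "n_removed", "n_true_assignments", "n_scored_assignments"):
            setattr(agg, attr, getattr(agg, attr) + getattr(outcome, attr))

        est = estimated_proportions(outcome, truth)
        tru = true_proportions(truth)
        err = (est.reindex(columns=tru.columns, fill_value=0.0) - tru).abs()
        max_prop_err = max(max_prop_err, float(err.to_numpy().max()))
        sums = est.sum(axis=1)
        max_sum_err = max(max_sum_err,
                          float((sums[sums > 0] - 1.0).abs().max()))

        prof = station_profile_from_counts(truth, outcome, packages, totals)
        lm = prof.landmarks(deep_clade=DEEP_CLADE_NAME)
        landmark_rows.append((truth.station, truth.z_star, lm["z_negmax"],
                              lm["z_lli"], lm["z_onset"]))

    landmarks = pd.DataFrame(landmark_rows, columns=["station", "z_star",
                                                     "z_negmax", "z_lli",
                                                     "z_onset"])
    complete = landmarks.dropna()
    if len(complete) >= 3:
        reg = linear_regression(complete["z_lli"], complete["z_onset"])
        r2, p = reg.r_squared, reg.p_value
    else:
        r2, p = float("nan"), float("nan")
    return ValidationReport(
        assignment_accuracy=agg.assignment_accuracy,
        removed_fraction=agg.removed_fraction,
        proportion_max_abs_error=max_prop_err,
        proportion_sum_error=max_sum_err,
        landmarks=landmarks, grid_step=depth_step,
        landmark_regression_r2=r2, landmark_regression_p=p,
        funnel={"reads": agg.n_reads, "recruited": agg.n_recruited,
                "placed": agg.n_placed, "kept": agg.n_kept,
                "removed": agg.n_removed})
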