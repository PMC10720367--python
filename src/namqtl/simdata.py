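"""Synthetic NAM genotypes, planted QTL and multi-environment trials.

The generator emulates a durum-wheat nested association mapping panel:
one recurrent parent crossed to several donors, each cross selfed to
F5-derived recombinant inbred lines (RILs), genotyped on a dense SNP
map, and phenotyped across environments in an augmented block design
with replicated parental checks.  Crossovers follow a Poisson process
with no interference (Haldane model), so closed-form oracles exist for
recombination fractions and residual heterozygosity.

Genotype coding: dosage of the recurrent-parent allele, 0/1/2, with
NaN for missing calls.  Haplotypes are internally 0/1 vectors (1 =
recurrent allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CHROMOSOMES = ("1A", "1B", "2A", "2B", "3A", "3B", "4A", "4B",
               "5A", "5B", "6A", "6B", "7A", "7B")
# per-chromosome genetic lengths (cM); sum 1,723 with 7A longest (179)
# and 4B shortest (51), matching a typical tetraploid consensus map
CHROM_LENGTHS_CM = (130, 135, 150, 145, 140, 120, 110, 51,
                    125, 118, 105, 100, 179, 115)
N_MARKERS_DEFAULT = 1678


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class GeneticMap:
    """Ordered marker positions, one row per marker."""

    table: pd.DataFrame  # columns: chromosome, marker_id, position_cM, [position_bp]

    def __post_init__(self) -> None:
        t = self.table
        required = {"chromosome", "marker_id", "position_cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if (t["position_cM"] < 0).any():
            raise ValueError("negative cM position")
        self.table = (
            t.sort_values(["chromosome", "position_cM"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def chrom_slice(self, chrom: str) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return sub

    def length_cM(self, chrom: str | None = None) -> float:
        if chrom is not None:
            pos = self.chrom_slice(chrom)["position_cM"].to_numpy()
            return float(pos.max() - pos.min())
        return float(sum(self.length_cM(c) for c in self.chromosomes))

    def chrom_arrays(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """Cached (chromosome, row indices, cM positions) triples in map order."""
        cached = getattr(self, "_chrom_arrays", None)
        if cached is None:
            cached = []
            chrom_col = self.table["chromosome"].to_numpy()
            pos_col = self.table["position_cM"].to_numpy()
            for c in self.chromosomes:
                idx = np.flatnonzero(chrom_col == c)
                cached.append((c, idx, pos_col[idx]))
            object.__setattr__(self, "_chrom_arrays", cached)
        return cached


@dataclass
class ParentSet:
    recurrent_id: str
    donor_ids: list[str]
    haplotypes: dict[str, np.ndarray]  # parent -> 0/1 haplotype over map markers

    def __post_init__(self) -> None:
        for pid, h in self.haplotypes.items():
            if not np.isin(h, (0, 1)).all():
                raise ValueError(f"parent {pid} not fully homozygous-coded")

    @property
    def parent_ids(self) -> list[str]:
        return [self.recurrent_id] + list(self.donor_ids)


@dataclass
class PlantedQtl:
    trait: str
    chromosome: str
    position_cM: float
    additive_effect: float  # trait units per recurrent-allele copy
    donor_scope: tuple[str, ...] | None = None  # crosses where the donor differs

    def __post_init__(self) -> None:
        if not np.isfinite(self.additive_effect):
            raise ValueError("QTL effect must be finite")


@dataclass
class EnvSpec:
    """One trial environment: moisture class, layout and noise structure."""

    env_id: str
    moisture_class: str  # "stressed" | "non_stressed"
    main_effect: dict[str, float]
    ipca_loading: np.ndarray
    blocks: int = 10
    block_size: int = 48
    check_ids: tuple[str, ...] = ()
    spatial_trend: dict[str, tuple[float, float]] = field(default_factory=dict)
    residual_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.moisture_class not in ("stressed", "non_stressed"):
            raise ValueError("moisture_class must be stressed/non_stressed")
        if any(s <= 0 for s in self.residual_sd.values()):
            raise ValueError("residual_sd must be positive")


@dataclass
class SimConfig:
    n_rils_per_cross: tuple[int, ...] = (146, 138, 142)
    inbreeding_generations: int = 4  # selfings: F5-derived RILs
    missing_rate: float = 0.005
    genotyping_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inbreeding_generations < 0:
            raise ValueError("inbreeding_generations must be >= 0")
        if not 0 <= self.missing_rate <= 0.05:
            raise ValueError("missing_rate must be in [0, 0.05]")


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage calls (0/1/2, NaN missing)."""

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # float, NaN = missing
    subfamily: np.ndarray | None = None  # per-line labels

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("calls shape inconsistent with ids")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("invalid call codes (expect 0/1/2/NaN)")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.line_ids, columns=self.marker_ids)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not present") from None

    def subset_lines(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [l for l, m in zip(self.line_ids, mask) if m],
            list(self.marker_ids),
            self.calls[mask],
            None if self.subfamily is None else self.subfamily[mask],
        )


@dataclass
class NamSimResult:
    genotypes: GenotypeMatrix        # observed (missing + error injected)
    true_genotypes: GenotypeMatrix   # error-free, complete
    pedigree: pd.DataFrame           # line_id, subfamily, donor, is_parent


# ---------------------------------------------------------------------------
# map and parents


def default_map(n_markers: int = N_MARKERS_DEFAULT) -> GeneticMap:
    """Evenly spaced consensus-style map: 14 chromosomes, 1,723 cM total."""
    total = sum(CHROM_LENGTHS_CM)
    counts = [max(2, int(round(n_markers * L / total))) for L in CHROM_LENGTHS_CM]
    # nudge counts so they sum exactly
    i = 0
    while sum(counts) != n_markers:
        counts[i % len(counts)] += 1 if sum(counts) < n_markers else -1
        i += 1
    rows = []
    for chrom, L, n in zip(CHROMOSOMES, CHROM_LENGTHS_CM, counts):
        pos = np.linspace(0.0, float(L), n)
        for j, p in enumerate(pos):
            rows.append((chrom, f"snp_{chrom}_{j:04d}", float(p),
                         int(round(p * 6e5)) + 1))
    return GeneticMap(pd.DataFrame(rows, columns=[
        "chromosome", "marker_id", "position_cM", "position_bp"]))


def make_parents(
    gmap: GeneticMap,
    rng: np.random.Generator,
    recurrent_id: str = "Nachit",
    donor_ids: Sequence[str] = ("DAWRYT110", "Faraj", "Jabal"),
    donor_poly_rate: float = 0.6,
) -> ParentSet:
    """Homozygous parents; every marker polymorphic in at least one cross."""
    m = gmap.n_markers
    haps = {recurrent_id: np.ones(m, dtype=np.int8)}
    donor_alleles = np.ones((len(donor_ids), m), dtype=np.int8)
    carry = rng.random((len(donor_ids), m)) < donor_poly_rate
    none = ~carry.any(axis=0)
    if none.any():  # force at least one donor to differ at every marker
        forced = rng.integers(0, len(donor_ids), size=int(none.sum()))
        carry[forced, np.where(none)[0]] = True
    donor_alleles[carry] = 0
    for d, row in zip(donor_ids, donor_alleles):
        haps[d] = row
    ps = ParentSet(recurrent_id, list(donor_ids), haps)
    for d in donor_ids:
        for chrom in gmap.chromosomes:
            idx = gmap.chrom_slice(chrom).index.to_numpy()
            if (haps[d][idx] == haps[recurrent_id][idx]).all():
                raise ValueError(f"donor {d} identical to recurrent on {chrom}")
    return ps


# ---------------------------------------------------------------------------
# meiosis and inbreeding


def simulate_gamete(
    hap_a: np.ndarray, hap_b: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a pair of haplotypes: Poisson crossovers, no interference."""
    if len(hap_a) != gmap.n_markers or len(hap_b) != gmap.n_markers:
        raise ValueError("haplotype length does not match map")
    out = np.empty(gmap.n_markers, dtype=hap_a.dtype)
    stacked = np.stack([hap_a, hap_b])
    for _chrom, idx, pos in gmap.chrom_arrays():
        length_morgan = (pos.max() - pos.min()) / 100.0
        n_xo = rng.poisson(length_morgan)
        start = rng.integers(0, 2)
        if n_xo == 0:
            out[idx] = stacked[start, idx]
            continue
        xo = np.sort(rng.uniform(pos.min(), pos.max(), size=n_xo))
        phase = (start + np.searchsorted(xo, pos, side="left")) % 2
        out[idx] = stacked[phase, idx]
    return out


def derive_ril(
    hap_p1: np.ndarray,
    hap_p2: np.ndarray,
    gmap: GeneticMap,
    generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Self an F1 for `generations` rounds; return 0/1/2 dosage genotype."""
    h1 = simulate_gamete(hap_p1, hap_p1, gmap, rng)  # parents homozygous
    h2 = simulate_gamete(hap_p2, hap_p2, gmap, rng)
    for _ in range(generations):
        g1 = simulate_gamete(h1, h2, gmap, rng)
        g2 = simulate_gamete(h1, h2, gmap, rng)
        h1, h2 = g1, g2
    return (h1 + h2).astype(np.int8)


def simulate_nam(
    parents: ParentSet, gmap: GeneticMap, config: SimConfig
) -> NamSimResult:
    """Simulate the full NAM: all crosses, parents appended, QC noise injected."""
    rng = np.random.default_rng(config.seed)
    if len(config.n_rils_per_cross) != len(parents.donor_ids):
        raise ValueError("one RIL count per donor cross required")
    rec = parents.haplotypes[parents.recurrent_id]
    line_ids: list[str] = []
    subfam: list[str] = []
    donor_of: list[str] = []
    rows: list[np.ndarray] = []
    counter = 1
    for donor, n in zip(parents.donor_ids, config.n_rils_per_cross):
        dh = parents.haplotypes[donor]
        fam = f"{parents.recurrent_id}/{donor}"
        for _ in range(n):
            rows.append(derive_ril(rec, dh, gmap, config.inbreeding_generations, rng))
            line_ids.append(f"NAM-{counter:03d}")
            subfam.append(fam)
            donor_of.append(donor)
            counter += 1
    for pid in parents.parent_ids:
        rows.append((2 * parents.haplotypes[pid]).astype(np.int8))
        line_ids.append(pid)
        subfam.append("parent")
        donor_of.append("")
    true_calls = np.array(rows, dtype=float)
    calls = true_calls.copy()
    if config.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < config.genotyping_error_rate
        calls[err] = rng.choice([0.0, 2.0], size=int(err.sum()))
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = np.nan
    subfam_arr = np.array(subfam)
    pedigree = pd.DataFrame({
        "line_id": line_ids,
        "subfamily": subfam,
        "donor": donor_of,
        "is_parent": [s == "parent" for s in subfam],
    })
    marker_ids = list(gmap.table["marker_id"])
    return NamSimResult(
        GenotypeMatrix(list(line_ids), marker_ids, calls, subfam_arr),
        GenotypeMatrix(list(line_ids), marker_ids, true_calls, subfam_arr),
        pedigree,
    )


# ---------------------------------------------------------------------------
# genetic values


def nearest_marker(gmap: GeneticMap, chromosome: str, position_cM: float) -> str:
    """Marker closest to a cM position; ties resolve to the lower cM marker."""
    sub = gmap.chrom_slice(chromosome)
    pos = sub["position_cM"].to_numpy()
    d = np.abs(pos - position_cM)
    best = np.flatnonzero(d == d.min())
    return str(sub["marker_id"].iloc[best[0]])


def genetic_values(
    genotypes: GenotypeMatrix, planted_qtl: Sequence[PlantedQtl], gmap: GeneticMap
) -> pd.DataFrame:
    """Purely additive genetic values: sum of effect x dosage at nearest marker."""
    traits = sorted({q.trait for q in planted_qtl})
    out = pd.DataFrame(0.0, index=genotypes.line_ids, columns=traits or ["value"])
    for q in planted_qtl:
        mk = nearest_marker(gmap, q.chromosome, q.position_cM)
        dose = genotypes.calls[:, genotypes.marker_index(mk)]
        if np.isnan(dose).any():
            raise ValueError("genetic values need complete (true) genotypes")
        out[q.trait] += q.additive_effect * dose
    return out


# ---------------------------------------------------------------------------
# trials and climate


def default_env_specs(
    check_ids: Sequence[str],
    n_stressed: int = 5,
    n_non_stressed: int = 3,
    rng: np.random.Generator | None = None,
) -> list[EnvSpec]:
    """Eight trial environments: five terminal-drought, three irrigated.

    Main effects place grain yield near 2,520 kg/ha under stress and
    4,251 kg/ha without, and TKW near 43 vs 45 g, the magnitude of a
    severe Mediterranean terminal drought.
    """
    rng = rng or np.random.default_rng(0)
    specs = []
    names = [f"Str{i+1}" for i in range(n_stressed)] + [
        f"Irr{i+1}" for i in range(n_non_stressed)]
    for j, name in enumerate(names):
        stressed = j < n_stressed
        gy_mu = 2520.0 if stressed else 4251.0
        tkw_mu = 43.0 if stressed else 45.0
        loading = np.array([
            (1.0 if stressed else -1.4) + rng.normal(0, 0.3),
            rng.normal(0, 0.5),
        ])
        specs.append(EnvSpec(
            env_id=name,
            moisture_class="stressed" if stressed else "non_stressed",
            main_effect={
                "TKW": tkw_mu, "GY": gy_mu, "DtH": 105.0 + rng.normal(0, 3),
                "DtM": 145.0 + rng.normal(0, 3), "PLH": 85.0 + rng.normal(0, 4),
                "Spk.m2": 320.0 + rng.normal(0, 15),
            },
            ipca_loading=loading,
            check_ids=tuple(check_ids),
            spatial_trend={"TKW": (0.05, 0.03), "GY": (8.0, 5.0)},
            residual_sd={"TKW": 2.0, "GY": 250.0, "DtH": 1.5, "DtM": 1.8,
                         "PLH": 4.0, "Spk.m2": 25.0},
        ))
    return specs


# interaction scale per trait: sqrt of the G x E variance component it plants
DEFAULT_INTERACTION_SD = {"TKW": 0.7, "GY": 150.0, "DtH": 0.5, "DtM": 0.5,
                          "PLH": 1.5, "Spk.m2": 8.0}
# per-line polygenic SD added on top of planted QTL; TKW/GY chosen so the
# entry-mean heritabilities land near the strongly contrasting magnitudes
# typical of these traits under terminal drought (TKW high, GY moderate)
DEFAULT_POLYGENIC_SD = {"TKW": 1.5, "GY": 110.0, "DtH": 2.5, "DtM": 2.5,
                        "PLH": 6.0, "Spk.m2": 20.0}
PLOT_AREA_M2 = 1.5


def default_planted_qtl() -> list[PlantedQtl]:
    """Three TKW loci (distinct chromosomes) plus two GY loci."""
    return [
        PlantedQtl("TKW", "1B", 120.0, 1.5),
        PlantedQtl("TKW", "6A", 65.0, 1.2),
        PlantedQtl("TKW", "7A", 9.0, 1.0),
        PlantedQtl("GY", "2B", 120.0, 60.0),
        PlantedQtl("GY", "5A", 6.0, 50.0),
    ]


def full_genetic_values(
    true_genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    planted_qtl: Sequence[PlantedQtl],
    rng: np.random.Generator,
    polygenic_sd: dict[str, float] | None = None,
) -> pd.DataFrame:
    """QTL values plus a polygenic term for every simulated trait."""
    polygenic_sd = polygenic_sd or DEFAULT_POLYGENIC_SD
    gv = genetic_values(true_genotypes, planted_qtl, gmap)
    n = true_genotypes.n_lines
    out = pd.DataFrame(index=true_genotypes.line_ids)
    for trait, sd in polygenic_sd.items():
        base = gv[trait].to_numpy() if trait in gv.columns else 0.0
        out[trait] = base + rng.normal(0.0, sd, size=n)
    # DtM must not fall below DtH: couple them
    out["DtM"] = out["DtH"] * 0.4 + out["DtM"] * 0.6 + 2.0
    return out


def _layout_entries(
    entries: Sequence[str], spec: EnvSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Augmented design: each block replicates every check; spares are checks."""
    checks = list(spec.check_ids)
    test_entries = [e for e in entries if e not in checks]
    capacity = spec.blocks * spec.block_size
    need = len(test_entries) + spec.blocks * len(checks)
    if need > capacity:
        raise ValueError(
            f"{spec.env_id}: layout capacity {capacity} < required {need}")
    per_block = np.array_split(rng.permutation(np.array(test_entries, dtype=object)),
                               spec.blocks)
    plots: list[tuple[int, str, bool]] = []
    spare = capacity - need
    extra = list(np.resize(np.array(checks, dtype=object), spare)) if spare else []
    for b in range(spec.blocks):
        block_entries = list(per_block[b]) + checks + extra[
            b * spare // spec.blocks: (b + 1) * spare // spec.blocks]
        # pad/truncate defensively to the block size
        block_entries = block_entries[: spec.block_size]
        while len(block_entries) < spec.block_size:
            block_entries.append(checks[len(block_entries) % len(checks)])
        order = rng.permutation(len(block_entries))
        for slot, k in enumerate(order):
            plots.append((b, block_entries[k], block_entries[k] in checks))
    ncols = 24 if capacity % 24 == 0 else spec.block_size
    rows = []
    for i, (b, entry, is_check) in enumerate(plots):
        rows.append((b + 1, i // ncols + 1, i % ncols + 1, entry, is_check))
    return pd.DataFrame(rows, columns=["block", "row", "column", "entry_id",
                                       "is_check"])


def _climate_series(
    spec: EnvSpec, rng: np.random.Generator, sowing: str = "2019-11-20"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily weather covering the four growth-stage windows.

    Stressed sites draw <=20 mm total rain after flowering (grain fill);
    non-stressed sites draw 40-90 mm, emulating supplemental irrigation.
    """
    sow = pd.Timestamp(sowing)
    bounds = {
        "pre_sowing": (sow - pd.Timedelta(days=30), sow),
        "vegetative": (sow, sow + pd.Timedelta(days=120)),
        "flowering": (sow + pd.Timedelta(days=120), sow + pd.Timedelta(days=135)),
        "grain_fill": (sow + pd.Timedelta(days=135), sow + pd.Timedelta(days=180)),
    }
    stage_rows = [(spec.env_id, s, a, b) for s, (a, b) in bounds.items()]
    days = pd.date_range(bounds["pre_sowing"][0],
                         bounds["grain_fill"][1] - pd.Timedelta(days=1), freq="D")
    doy = np.arange(len(days))
    tmax = 16 + 12 * np.sin((doy - 40) / len(days) * np.pi) + rng.normal(0, 2, len(days))
    tmin = tmax - 10 - rng.normal(2, 1, len(days))
    stressed = spec.moisture_class == "stressed"
    totals = {
        "pre_sowing": rng.uniform(10, 40),
        "vegetative": rng.uniform(120, 250),
        "flowering": rng.uniform(2, 10) if stressed else rng.uniform(15, 40),
        "grain_fill": rng.uniform(5, 20) if stressed else rng.uniform(40, 90),
    }
    rain = np.zeros(len(days))
    for stage, (a, b) in bounds.items():
        in_win = (days >= a) & (days < b)
        w = rng.random(int(in_win.sum())) ** 3  # a few wet days carry most rain
        rain[in_win] = totals[stage] * w / w.sum()
    daily = pd.DataFrame({"site": spec.env_id, "date": days,
                          "tmin": tmin, "tmax": tmax, "rain": rain})
    stages = pd.DataFrame(stage_rows, columns=["env_id", "stage", "start", "end"])
    return daily, stages


def simulate_trials(
    genetic_vals: pd.DataFrame,
    env_specs: Sequence[EnvSpec],
    rng: np.random.Generator,
    interaction_sd: dict[str, float] | None = None,
    plot_area: float = PLOT_AREA_M2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plot-level trial table plus daily climate and stage-date tables.

    Plot value = env main effect + genotype value + sum_k lambda_k *
    g_score_k * env_loading_k + row/col trend + residual.  Trait values
    are then re-expressed as the raw field measures (kernel sample
    weight, plot grain weight, spike row counts, phenology dates).
    """
    interaction_sd = interaction_sd or DEFAULT_INTERACTION_SD
    entries = list(genetic_vals.index)
    n_axes = len(env_specs[0].ipca_loading)
    gscore = pd.DataFrame(rng.normal(size=(len(entries), n_axes)), index=entries)
    env_parts, climate_parts, stage_parts = [], [], []
    for spec in env_specs:
        layout = _layout_entries(entries, spec, rng)
        daily, stages = _climate_series(spec, rng)
        climate_parts.append(daily)
        stage_parts.append(stages)
        load = np.asarray(spec.ipca_loading)
        inter_score = gscore.loc[layout["entry_id"]].to_numpy() @ load
        row = layout["row"].to_numpy()
        col = layout["column"].to_numpy()
        n = len(layout)
        vals = {}
        for trait in spec.main_effect:
            g = genetic_vals.loc[layout["entry_id"], trait].to_numpy()
            rs, cs = spec.spatial_trend.get(trait, (0.0, 0.0))
            vals[trait] = (spec.main_effect[trait] + g
                           + interaction_sd.get(trait, 0.0) * inter_score
                           + rs * row + cs * col
                           + rng.normal(0.0, spec.residual_sd[trait], size=n))
        vals["DtM"] = np.maximum(vals["DtM"], vals["DtH"] + 5.0)
        env_parts.append(pd.DataFrame({
            "env_id": spec.env_id, "block": layout["block"], "row": row,
            "column": col, "entry_id": layout["entry_id"],
            "is_check": layout["is_check"].astype(bool),
            "DtH": np.round(vals["DtH"]), "DtM": np.round(vals["DtM"]),
            "PLH": vals["PLH"],
            "spike_row_count": np.maximum(vals["Spk.m2"], 4.0) / 4.0,
            "plot_grain_weight": np.maximum(vals["GY"], 50.0) * plot_area / 1e4,
            "plot_area": plot_area,
            "kernel_sample_weight": np.maximum(vals["TKW"], 5.0) / 5.0,
        }))
    plots = pd.concat(env_parts, ignore_index=True)
    return plots, pd.concat(climate_parts, ignore_index=True), pd.concat(
        stage_parts, ignore_index=True)


@dataclass
class NamStudy:
    """A full synthetic study bundle used by the pipeline and drivers."""

    gmap: GeneticMap
    parents: ParentSet
    planted_qtl: list[PlantedQtl]
    sim: NamSimResult
    env_specs: list[EnvSpec]
    plots: pd.DataFrame
    climate: pd.DataFrame
    stage_dates: pd.DataFrame
    genetic_vals: pd.DataFrame


def simulate_study(
    seed: int = 0,
    n_markers: int = N_MARKERS_DEFAULT,
    config: SimConfig | None = None,
    planted_qtl: Sequence[PlantedQtl] | None = None,
    n_stressed: int = 5,
    n_non_stressed: int = 3,
) -> NamStudy:
    """End-to-end default study: map, parents, NAM, trials, climate."""
    config = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed + 1)
    gmap = default_map(n_markers)
    parents = make_parents(gmap, rng)
    sim = simulate_nam(parents, gmap, config)
    qtl = list(planted_qtl) if planted_qtl is not None else default_planted_qtl()
    gv = full_genetic_values(sim.true_genotypes, gmap, qtl, rng)
    specs = default_env_specs(parents.parent_ids, n_stressed, n_non_stressed, rng)
    plots, climate, stages = simulate_trials(gv, specs, rng)
    return NamStudy(gmap, parents, qtl, sim, specs, plots, climate, stages, gv)
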