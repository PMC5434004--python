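"""Synthetic genotype, haplotype-tract and IBD-segment generation with known truth.

The generator emulates a Mediterranean-style study design: several source
ancestries (European-like, Caucasian-like, Sardinian-like, Near-Eastern-like)
drift independently from a shared ancestral allele-frequency pool under the
Balding-Nichols model (star phylogeny); admixed target populations are built as
single-pulse mixtures whose haplotypes are Markov tract mosaics along a genetic
map (breakpoints Poisson at rate G per Morgan, tract ancestries i.i.d. from the
mixing proportions alpha); drifted isolates are recombined from a small founder
haplotype pool, which raises homozygosity and within-population sharing; and
cross-population IBD segments are planted with controllable rates and a
truncated-exponential length distribution.

All ground truth (per-population alpha, admixture date G, planted segments,
per-individual ancestry fractions, isolate flags) is recorded in a
:class:`ScenarioTruth` that serializes to JSON + segment TSV. Every operation
is a pure function of its parameters and seed.

The default genetic map is uniform at 1 cM/Mb over 22 synthetic chromosomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ibd_sharing import SEGMENT_COLUMNS, IBDSegmentSet, write_segments, read_segments
from .io_qc import GenotypeMatrix, make_samples


# ---------------------------------------------------------------------------
# Genetic map and variant placement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Chromosome lengths in cM; physical scale fixed at 1 cM/Mb."""

    chromosomes: tuple[str, ...]
    lengths_cM: tuple[float, ...]

    @property
    def total_cM(self) -> float:
        return float(sum(self.lengths_cM))

    def length_of(self, chrom: str) -> float:
        return self.lengths_cM[self.chromosomes.index(chrom)]


def uniform_map(n_chromosomes: int = 22, chrom_length_cM: float = 100.0) -> GeneticMap:
    return GeneticMap(
        tuple(str(i + 1) for i in range(n_chromosomes)),
        tuple(float(chrom_length_cM) for _ in range(n_chromosomes)),
    )


def variant_table(n_variants: int, gmap: GeneticMap) -> pd.DataFrame:
    """Evenly spaced variants along the map (deterministic placement).

    Variants are allotted to chromosomes proportionally to genetic length and
    placed on a regular cM grid; position_bp = cM * 1e6 (1 cM/Mb). Alleles are
    fixed A/G (unambiguous) since the generator works on 0/1 alleles.
    """
    total = sum(gmap.lengths_cM)
    counts = [int(round(n_variants * L / total)) for L in gmap.lengths_cM]
    # Largest-remainder style fixup to hit n_variants exactly.
    while sum(counts) > n_variants:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_variants:
        counts[int(np.argmin(counts))] += 1
    rows = []
    k = 0
    for chrom, L, m in zip(gmap.chromosomes, gmap.lengths_cM, counts):
        # Offset grid keeps sites strictly inside (0, L).
        cms = (np.arange(m) + 0.5) * (L / m) if m else np.array([])
        for cm in cms:
            rows.append(
                {
                    "id": f"rs{k}",
                    "chromosome": chrom,
                    "position_bp": int(round(cm * 1e6)),
                    "genetic_pos_cM": float(cm),
                    "allele_a": "A",
                    "allele_b": "G",
                }
            )
            k += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Balding-Nichols components
# ---------------------------------------------------------------------------


@dataclass
class ComponentModel:
    """One ancestry component: ancestral frequencies plus a drifted realization.

    ``freqs`` are the component's own allele_b frequencies, drawn around
    ``ancestral_freqs`` under the Balding-Nichols Beta model at the given FST.
    """

    name: str
    ancestral_freqs: np.ndarray
    fst: float
    freqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.freqs is None:
            self.freqs = self.ancestral_freqs.copy()
        if len(self.freqs) != len(self.ancestral_freqs):
            raise ValueError("frequency vector length mismatch")


def _draw_ancestral(n_variants: int, maf_range: tuple[float, float], rng) -> np.ndarray:
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    maf = rng.uniform(lo, hi, n_variants)
    # Random fold so allele_b is minor or major with equal probability.
    flip = rng.random(n_variants) < 0.5
    return np.where(flip, 1.0 - maf, maf)


def _drift(p: np.ndarray, fst: float, rng) -> np.ndarray:
    if fst == 0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    out = rng.beta(a, b)
    # Keep strictly inside (0,1) so downstream likelihoods stay finite.
    return np.clip(out, 1e-9, 1.0 - 1e-9)


def make_component_freqs(
    n_variants: int,
    fst: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    name: str = "component",
) -> ComponentModel:
    """Draw one component: ancestral freqs uniform on the folded MAF range,
    then a Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) drift realization."""
    if not (0 <= fst < 1):
        raise ValueError("fst must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    anc = _draw_ancestral(n_variants, maf_range, rng)
    return ComponentModel(name, anc, fst, _drift(anc, fst, rng))


def make_component_set(
    names_fst: dict[str, float],
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> list[ComponentModel]:
    """Components drifting independently from ONE shared ancestral pool
    (star phylogeny) — the structure the f3 admixture screen assumes."""
    rng = np.random.default_rng(seed)
    anc = _draw_ancestral(n_variants, maf_range, rng)
    return [
        ComponentModel(name, anc, fst, _drift(anc, fst, rng))
        for name, fst in names_fst.items()
    ]


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------


def simulate_unadmixed(
    component: ComponentModel,
    n_individuals: int,
    seed: int = 0,
    variants: pd.DataFrame | None = None,
    population: str | None = None,
    id_prefix: str | None = None,
) -> GenotypeMatrix:
    """Individuals drawn Binomial(2, p_s) per site from the component's frequencies."""
    rng = np.random.default_rng(seed)
    p = component.freqs
    calls = rng.binomial(2, p, size=(n_individuals, len(p))).astype(np.int16)
    pop = population or component.name
    prefix = id_prefix or pop
    samples = make_samples([f"{prefix}_{i}" for i in range(n_individuals)], [pop] * n_individuals)
    if variants is None:
        variants = variant_table(len(p), uniform_map())
    return GenotypeMatrix(samples, variants, calls)


@dataclass
class HaplotypePanel:
    """Phased haplotypes with their local-ancestry tract decomposition.

    ``haplotypes``: (n_individuals, 2, n_variants) alleles in {0,1}.
    ``tracts``: DataFrame (individual, haplotype, chromosome, start_cM, end_cM,
    component); per haplotype and chromosome the tracts tile [0, L] exactly.
    """

    haplotypes: np.ndarray
    tracts: pd.DataFrame
    component_names: list[str]


def simulate_admixed(
    components: list[ComponentModel],
    alpha: np.ndarray,
    G: int,
    gmap: GeneticMap,
    n_individuals: int,
    seed: int = 0,
    variants: pd.DataFrame | None = None,
    population: str = "admixed",
    id_prefix: str | None = None,
) -> tuple[GenotypeMatrix, HaplotypePanel]:
    """Single-pulse admixture G generations ago with proportions *alpha*.

    Each haplotype is a Markov tract mosaic: breakpoints are a Poisson process
    at rate G per Morgan along the genetic map and tract ancestries are i.i.d.
    categorical(alpha); alleles within a tract are Bernoulli draws from the
    tract component's frequency. Returns the diploid genotypes plus the full
    haplotype/tract truth.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or len(alpha) != len(components):
        raise ValueError("alpha must give one proportion per component")
    if not np.isclose(alpha.sum(), 1.0):
        raise ValueError("alpha must sum to 1")
    if G < 1:
        raise ValueError("G must be >= 1")
    if not gmap.chromosomes:
        raise ValueError("empty genetic map")
    rng = np.random.default_rng(seed)
    if variants is None:
        variants = variant_table(len(components[0].freqs), gmap)
    freq_stack = np.stack([c.freqs for c in components])  # (K, V)
    chrom_arr = variants["chromosome"].to_numpy()
    cm_arr = variants["genetic_pos_cM"].to_numpy()
    n_var = len(variants)
    haps = np.zeros((n_individuals, 2, n_var), dtype=np.int8)
    tract_rows = []
    for i in range(n_individuals):
        for h in range(2):
            for chrom, L in zip(gmap.chromosomes, gmap.lengths_cM):
                vidx = np.flatnonzero(chrom_arr == chrom)
                n_bp = rng.poisson(G * L / 100.0)
                breaks = np.sort(rng.uniform(0.0, L, n_bp))
                edges = np.concatenate([[0.0], breaks, [L]])
                comps = rng.choice(len(components), size=len(edges) - 1, p=alpha)
                for t in range(len(comps)):
                    tract_rows.append(
                        (i, h, chrom, edges[t], edges[t + 1], components[comps[t]].name)
                    )
                if len(vidx):
                    site_tract = np.searchsorted(breaks, cm_arr[vidx], side="right")
                    p_site = freq_stack[comps[site_tract], vidx]
                    haps[i, h, vidx] = rng.random(len(vidx)) < p_site
    calls = haps.sum(axis=1).astype(np.int16)
    prefix = id_prefix or population
    samples = make_samples(
        [f"{prefix}_{i}" for i in range(n_individuals)], [population] * n_individuals
    )
    tracts = pd.DataFrame(
        tract_rows,
        columns=["individual", "haplotype", "chromosome", "start_cM", "end_cM", "component"],
    )
    panel = HaplotypePanel(haps, tracts, [c.name for c in components])
    return GenotypeMatrix(samples, variants, calls), panel


def simulate_isolate(
    source_component: ComponentModel,
    founder_haplotypes: int,
    n_individuals: int,
    seed: int = 0,
    variants: pd.DataFrame | None = None,
    gmap: GeneticMap | None = None,
    population: str = "isolate",
    switch_rate_per_M: float = 1.0,
) -> GenotypeMatrix:
    """A drifted isolate: individuals recombined from a small founder pool.

    ``founder_haplotypes`` haplotypes are drawn once from the source
    component; every individual's haplotypes are mosaics of that pool
    (founder switches Poisson at *switch_rate_per_M* per Morgan). The limited
    pool elevates homozygosity runs and within-population sharing relative to
    a panmictic sample of the same component.
    """
    if founder_haplotypes < 2:
        raise ValueError("founder pool must contain at least 2 haplotypes")
    rng = np.random.default_rng(seed)
    gmap = gmap or uniform_map()
    p = source_component.freqs
    if variants is None:
        variants = variant_table(len(p), gmap)
    pool = (rng.random((founder_haplotypes, len(p))) < p).astype(np.int8)
    chrom_arr = variants["chromosome"].to_numpy()
    cm_arr = variants["genetic_pos_cM"].to_numpy()
    haps = np.zeros((n_individuals, 2, len(p)), dtype=np.int8)
    for i in range(n_individuals):
        for h in range(2):
            for chrom, L in zip(gmap.chromosomes, gmap.lengths_cM):
                vidx = np.flatnonzero(chrom_arr == chrom)
                if not len(vidx):
                    continue
                n_bp = rng.poisson(switch_rate_per_M * L / 100.0)
                breaks = np.sort(rng.uniform(0.0, L, n_bp))
                founders = rng.integers(0, founder_haplotypes, size=len(breaks) + 1)
                site_tract = np.searchsorted(breaks, cm_arr[vidx], side="right")
                haps[i, h, vidx] = pool[founders[site_tract], vidx]
    calls = haps.sum(axis=1).astype(np.int16)
    samples = make_samples(
        [f"{population}_{i}" for i in range(n_individuals)], [population] * n_individuals
    )
    return GenotypeMatrix(samples, variants, calls)


# ---------------------------------------------------------------------------
# IBD segment planting
# ---------------------------------------------------------------------------


def plant_ibd_segments(
    populations: dict[str, list[str]],
    pair_rate: float,
    mean_length_cM: float = 2.5,
    min_length_cM: float = 1.0,
    seed: int = 0,
    gmap: GeneticMap | None = None,
    population_pairs: list[tuple[str, str]] | None = None,
) -> IBDSegmentSet:
    """Plant IBD segments between individual pairs with known truth.

    For every individual pair spanned by *population_pairs* (default: all
    unordered population pairs, within-population included), the segment count
    is Poisson(*pair_rate*) and lengths follow an exponential of mean
    *mean_length_cM* left-truncated at *min_length_cM* (by memorylessness,
    length = min + Exp(mean)). Segments are placed uniformly on the map.
    """
    if mean_length_cM <= 0:
        raise ValueError("mean_length_cM must be positive")
    rng = np.random.default_rng(seed)
    gmap = gmap or uniform_map()
    pops = sorted(populations)
    if population_pairs is None:
        population_pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i:]]
    lengths = np.array(gmap.lengths_cM)
    probs = lengths / lengths.sum()
    rows = []
    for pa, pb in population_pairs:
        if pa == pb:
            members = populations[pa]
            pairs = [
                (members[i], members[j])
                for i in range(len(members))
                for j in range(i + 1, len(members))
            ]
        else:
            pairs = [(x, y) for x in populations[pa] for y in populations[pb]]
        for s1, s2 in pairs:
            for _ in range(rng.poisson(pair_rate)):
                ln = min_length_cM + rng.exponential(mean_length_cM)
                ci = rng.choice(len(lengths), p=probs)
                L = lengths[ci]
                ln = min(ln, L)  # clip to chromosome
                start = rng.uniform(0.0, L - ln) if L > ln else 0.0
                rows.append((s1, s2, gmap.chromosomes[ci], start, start + ln))
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return IBDSegmentSet(df, provenance="planted")


# ---------------------------------------------------------------------------
# Scenario ground truth
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """A fully generated study: genotypes, segment calls and ground truth."""

    genotypes: GenotypeMatrix
    segments: IBDSegmentSet
    truth: ScenarioTruth
    components: list[ComponentModel]
    gmap: GeneticMap
    panels: dict[str, "HaplotypePanel"] = field(default_factory=dict)


_SCENARIO_KEYS = {
    "seed",
    "n_variants",
    "n_chromosomes",
    "chrom_length_cM",
    "maf_range",
    "components",
    "populations",
    "ibd",
}
_POP_KEYS = {"name", "type", "component", "alpha", "G", "n", "founders"}
_IBD_KEYS = {"seed", "base_pair_rate", "mean_length_cM", "min_length_cM", "boosts"}


def default_scenario_config() -> dict:
    """The bundled "mediterranean-toy" design: four source ancestries, two
    admixed targets with known dates, one founder-effect isolate, and planted
    IBD with an excess between the isolate-side group and one comparison."""
    return {
        "seed": 7,
        "n_variants": 4000,
        "n_chromosomes": 8,
        "chrom_length_cM": 100.0,
        "maf_range": [0.05, 0.5],
        "components": {
            "european": 0.08,
            "caucasian": 0.10,
            "sardinian": 0.12,
            "near_eastern": 0.10,
        },
        "populations": [
            {"name": "euro_a", "type": "unadmixed", "component": "european", "n": 25},
            {"name": "cauc_a", "type": "unadmixed", "component": "caucasian", "n": 25},
            {"name": "sard_a", "type": "unadmixed", "component": "sardinian", "n": 25},
            {"name": "near_a", "type": "unadmixed", "component": "near_eastern", "n": 25},
            {
                "name": "mixed_en",
                "type": "admixed",
                "alpha": {"european": 0.5, "near_eastern": 0.5},
                "G": 20,
                "n": 25,
            },
            {
                "name": "mixed_sc",
                "type": "admixed",
                "alpha": {"sardinian": 0.7, "caucasian": 0.3},
                "G": 40,
                "n": 25,
            },
            {"name": "isolate_gr", "type": "isolate", "component": "european", "n": 20, "founders": 10},
        ],
        "ibd": {
            "seed": 11,
            "base_pair_rate": 0.15,
            "mean_length_cM": 2.5,
            "min_length_cM": 1.0,
            "boosts": [
                {"pop1": "isolate_gr", "pop2": "isolate_gr", "pair_rate": 2.0},
                {"pop1": "mixed_en", "pop2": "near_a", "pair_rate": 1.0},
            ],
        },
    }


def generate_scenario(config: dict | None = None) -> Scenario:
    """Generate a complete synthetic study from a validated scenario config."""
    config = config if config is not None else default_scenario_config()
    unknown = set(config) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario key(s): {sorted(unknown)}")
    if "seed" not in config:
        raise ValueError("scenario config must set an explicit seed")
    seed = int(config["seed"])
    gmap = uniform_map(
        int(config.get("n_chromosomes", 22)), float(config.get("chrom_length_cM", 100.0))
    )
    n_variants = int(config.get("n_variants", 4000))
    variants = variant_table(n_variants, gmap)
    components = make_component_set(
        {str(k): float(v) for k, v in config["components"].items()},
        n_variants,
        tuple(config.get("maf_range", (0.05, 0.5))),
        seed=seed,
    )
    comp_by_name = {c.name: c for c in components}
    comp_names = [c.name for c in components]

    parts: list[GenotypeMatrix] = []
    panels: dict[str, HaplotypePanel] = {}
    alpha_truth: dict[str, dict[str, float]] = {}
    dates: dict[str, int] = {}
    isolates: list[str] = []
    q_rows = []
    for k, popcfg in enumerate(config["populations"]):
        unknown = set(popcfg) - _POP_KEYS
        if unknown:
            raise ValueError(f"unknown population key(s): {sorted(unknown)}")
        name, ptype, n = popcfg["name"], popcfg["type"], int(popcfg["n"])
        pop_seed = seed + 1000 * (k + 1)
        if ptype == "unadmixed":
            comp = comp_by_name[popcfg["component"]]
            gm = simulate_unadmixed(comp, n, seed=pop_seed, variants=variants, population=name)
            alpha_truth[name] = {c: float(c == comp.name) for c in comp_names}
        elif ptype == "admixed":
            alpha = np.array([popcfg["alpha"].get(c, 0.0) for c in comp_names])
            gm, panel = simulate_admixed(
                components, alpha, int(popcfg["G"]), gmap, n,
                seed=pop_seed, variants=variants, population=name,
            )
            panels[name] = panel
            alpha_truth[name] = {c: float(a) for c, a in zip(comp_names, alpha)}
            dates[name] = int(popcfg["G"])
        elif ptype == "isolate":
            comp = comp_by_name[popcfg["component"]]
            gm = simulate_isolate(
                comp, int(popcfg.get("founders", 10)), n,
                seed=pop_seed, variants=variants, gmap=gmap, population=name,
            )
            alpha_truth[name] = {c: float(c == comp.name) for c in comp_names}
            isolates.append(name)
        else:
            raise ValueError(f"unknown population type {ptype!r}")
        for sid in gm.samples["id"]:
            q_rows.append({"individual": sid, "population": name, **alpha_truth[name]})
        parts.append(gm)

    samples = pd.concat([p.samples for p in parts], ignore_index=True)
    calls = np.vstack([p.calls for p in parts])
    genotypes = GenotypeMatrix(samples, variants.copy(), calls)

    ibd_cfg = dict(config.get("ibd", {}))
    unknown = set(ibd_cfg) - _IBD_KEYS
    if unknown:
        raise ValueError(f"unknown ibd key(s): {sorted(unknown)}")
    pop_members = {
        p: genotypes.samples.loc[genotypes.samples["population"] == p, "id"].tolist()
        for p in genotypes.samples["population"].unique()
    }
    ibd_seed = int(ibd_cfg.get("seed", seed + 999))
    base = plant_ibd_segments(
        pop_members,
        float(ibd_cfg.get("base_pair_rate", 0.15)),
        float(ibd_cfg.get("mean_length_cM", 2.5)),
        float(ibd_cfg.get("min_length_cM", 1.0)),
        seed=ibd_seed,
        gmap=gmap,
    )
    frames = [base.segments]
    for j, boost in enumerate(ibd_cfg.get("boosts", [])):
        extra = plant_ibd_segments(
            pop_members,
            float(boost["pair_rate"]),
            float(ibd_cfg.get("mean_length_cM", 2.5)),
            float(ibd_cfg.get("min_length_cM", 1.0)),
            seed=ibd_seed + j + 1,
            gmap=gmap,
            population_pairs=[(boost["pop1"], boost["pop2"])],
        )
        frames.append(extra.segments)
    segments = IBDSegmentSet(pd.concat(frames, ignore_index=True), provenance="scenario")

    truth = ScenarioTruth(
        alpha=alpha_truth,
        dates=dates,
        planted_segments=segments,
        true_q=pd.DataFrame(q_rows),
        isolates=isolates,
    )
    return Scenario(genotypes, segments, truth, components, gmap, panels)


@dataclass
class ScenarioTruth:
    """Everything the generator knows that an analysis should recover."""

    alpha: dict[str, dict[str, float]]  # population -> component -> proportion
    dates: dict[str, int]  # population -> admixture generations G
    planted_segments: IBDSegmentSet
    true_q: pd.DataFrame  # columns: individual, population, one per component
    isolates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pop, a in self.alpha.items():
            if not np.isclose(sum(a.values()), 1.0):
                raise ValueError(f"alpha for {pop} does not sum to 1")
        for pop, g in self.dates.items():
            if g <= 0:
                raise ValueError(f"date for {pop} must be positive")

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        payload = {
            "alpha": self.alpha,
            "dates": self.dates,
            "isolates": self.isolates,
            "true_q": self.true_q.to_dict(orient="list"),
        }
        prefix.with_suffix(".truth.json").write_text(json.dumps(payload, indent=1))
        write_segments(self.planted_segments, prefix.with_suffix(".planted.tsv"))

    @classmethod
    def load(cls, prefix) -> "ScenarioTruth":
        prefix = Path(prefix)
        payload = json.loads(prefix.with_suffix(".truth.json").read_text())
        return cls(
            alpha=payload["alpha"],
            dates={k: int(v) for k, v in payload["dates"].items()},
            planted_segments=read_segments(prefix.with_suffix(".planted.tsv")),
            true_q=pd.DataFrame(payload["true_q"]),
            isolates=payload["isolates"],
        )
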