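"""Seeded synthetic cohorts with planted truth.

The generator emulates everything the pipeline consumes: a probe map
over a desk-scale genome (two autosomes plus X and Y with declared
PAR/XTR spans), two pseudo-callers that emit penn-style and
partition-style call files with boundary jitter, occasional splits,
misses and sub-threshold confidences, reference CNV sets seeded with
the planted common polymorphisms, a DGV-like catalogue, a synthetic
transcriptome and gene-set library with one planted enriched pathway,
per-sample probe intensity tables around planted events (log R ratio
state means -0.45 / +0.3, sd 0.133), sequence-variant tables with
binomial read counts, and a truth table assigning every planted event
its expected pipeline fate.

Everything derives from one ``numpy`` Generator seeded from the config,
and outputs are sorted before writing, so a fixed seed reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io_formats
from .intervals import GenomicInterval, reciprocal_overlap
from .models import (
    CnvCall,
    ProbeRecord,
    ReferenceSet,
    RegionMap,
    SequenceVariant,
)

__all__ = [
    "SyntheticCohortConfig",
    "PlantedEvent",
    "PlantedVariant",
    "SyntheticCohort",
    "generate_cohort",
    "generate_variants",
    "write_bundle",
    "SYNTHETIC_REGIONS",
]

#: Synthetic sex-chromosome structure (desk-scale X and Y).
SYNTHETIC_REGIONS = RegionMap(
    par=(
        GenomicInterval("X", 1, 300_000),
        GenomicInterval("Y", 1, 300_000),
    ),
    xtr=(GenomicInterval("X", 5_000_000, 5_500_000),),
)

# expected pipeline fates by planted class
FATE = {
    "rare_candidate": "retained_candidate",
    "sex_candidate": "retained_candidate",
    "common_cnp": "filtered_common",
    "dgv_like": "filtered_dgv",
    "small_size": "filtered_size",
    "low_probe": "filtered_probes",
    "artifact": "artifact_flagged",
    "par_diploid": "filtered_par_xtr",
}


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Noise parameters follow array-CNV practice: per-probe log R ratio
    sd 0.133 (the deviation reported for the emulated array data),
    state means -0.45 (single-copy loss) and +0.3 (single-copy gain),
    ~2 kb call-boundary jitter, a 5% per-caller miss probability and a
    10% chance of a below-threshold confidence score.
    """

    seed: int = 0
    n_cases: int = 20
    n_controls: int = 3
    chromosome_sizes: dict = field(
        default_factory=lambda: {
            "1": 60_000_000,
            "2": 45_000_000,
            "X": 12_000_000,
            "Y": 6_000_000,
        }
    )
    probe_spacing_bp: int = 2_000
    sparse_region: tuple = ("2", 30_000_000, 35_000_000)
    sparse_factor: int = 6
    # planted event counts per class
    n_rare: int = 8
    n_recurrent_pairs: int = 1
    n_common: int = 5
    n_dgv: int = 3
    n_small: int = 2
    n_low_probe: int = 2
    n_artifact: int = 2
    include_sex_events: bool = True
    # caller noise
    miss_prob: float = 0.05
    subthreshold_conf_prob: float = 0.10
    jitter_sd_bp: float = 2_000.0
    split_prob: float = 0.02
    fp_per_sample: float = 3.0
    # intensity model
    lrr_loss_mean: float = -0.45
    lrr_gain_mean: float = 0.30
    lrr_sd: float = 0.133
    # variant spec
    n_true_het: int = 30
    n_artifact_variants: int = 30
    n_common_variants: int = 5
    mean_depth: int = 60
    # gene sets
    n_gene_sets: int = 25
    gene_set_size: tuple = (10, 40)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PlantedEvent:
    event_id: str
    sample: str
    interval: GenomicInterval
    copy_number: int
    klass: str

    @property
    def expected_fate(self) -> str:
        return FATE[self.klass]


@dataclass
class PlantedVariant:
    variant: SequenceVariant
    klass: str  # true_het | artifact | common


@dataclass
class SyntheticCohort:
    """In-memory bundle; :func:`write_bundle` serializes it."""

    config: SyntheticCohortConfig
    samples: list
    sample_sex: dict
    probe_positions: dict  # chrom -> np.ndarray of positions
    penn_calls: list
    partition_calls: list
    references: dict  # name -> ReferenceSet
    dgv: ReferenceSet
    transcripts: list
    gene_universe: list
    gene_set_library: dict
    planted_set_name: str
    events: list  # PlantedEvent
    variants: list  # PlantedVariant
    probes_by_sample: dict  # sample -> list[ProbeRecord]
    candidate_gene_list: frozenset


# ---------------------------------------------------------------------------
# probe map


def _probe_positions(config: SyntheticCohortConfig) -> dict[str, np.ndarray]:
    positions = {}
    sp_chrom, sp_start, sp_end = config.sparse_region
    for chrom, size in config.chromosome_sizes.items():
        pos = np.arange(1_000, size, config.probe_spacing_bp, dtype=np.int64)
        if chrom == sp_chrom:
            inside = (pos >= sp_start) & (pos <= sp_end)
            sparse = pos[inside][:: config.sparse_factor]
            pos = np.sort(np.concatenate([pos[~inside], sparse]))
        positions[chrom] = pos
    return positions


def _count_probes(positions: dict[str, np.ndarray], iv: GenomicInterval) -> int:
    pos = positions.get(iv.chrom)
    if pos is None:
        return 0
    lo = np.searchsorted(pos, iv.start, side="left")
    hi = np.searchsorted(pos, iv.end, side="right")
    return int(hi - lo)


# ---------------------------------------------------------------------------
# event planting


def _place_events(config: SyntheticCohortConfig, rng, samples: list) -> list:
    """Lay out planted events along the autosomes with generous gaps.

    Chromosome 1 above 50 Mb is reserved for background reference-set
    entries so that planted rare events never collide with them; the
    sparse probe window hosts the low-probe class only.
    """
    sp_chrom, sp_start, sp_end = config.sparse_region
    size_ranges = {
        "rare_candidate": (40_000, 150_000),
        "common_cnp": (50_000, 120_000),
        "dgv_like": (40_000, 100_000),
        "artifact": (40_000, 80_000),
        "small_size": (8_000, 15_000),
    }
    plan: list[tuple[str, int]] = []
    for klass, n in (
        ("rare_candidate", config.n_rare),
        ("common_cnp", config.n_common),
        ("dgv_like", config.n_dgv),
        ("artifact", config.n_artifact),
        ("small_size", config.n_small),
    ):
        plan.extend((klass, i) for i in range(n))

    events: list[PlantedEvent] = []
    cursors = {"1": 1_000_000, "2": 1_000_000}
    limits = {"1": 50_000_000, "2": config.chromosome_sizes["2"] - 1_000_000}
    chrom_cycle = ["1", "2"]
    ci = 0
    gap = 400_000

    for klass, i in plan:
        lo, hi = size_ranges[klass]
        size = int(rng.integers(lo, hi + 1))
        chrom = chrom_cycle[ci % 2]
        ci += 1
        start = cursors[chrom]
        # keep clear of the sparse window on chromosome 2
        if chrom == sp_chrom and start + size > sp_start - 50_000 and start < sp_end + 50_000:
            start = sp_end + 100_000
        if start + size > limits[chrom]:
            chrom = "1" if chrom == "2" else "2"
            start = cursors[chrom]
        cursors[chrom] = start + size + gap
        interval = GenomicInterval(chrom, start, start + size - 1)
        copy_number = int(rng.choice([1, 3]))
        sample = str(rng.choice(samples))
        event_id = f"{klass}_{i:02d}"
        events.append(PlantedEvent(event_id, sample, interval, copy_number, klass))
        if klass == "rare_candidate" and i < config.n_recurrent_pairs:
            # plant a near-identical partner event in a second case
            others = [s for s in samples if s != sample]
            partner = str(rng.choice(others))
            shift = int(rng.integers(-2_000, 2_001))
            p_start = max(1, start + shift)
            events.append(
                PlantedEvent(
                    f"{klass}_{i:02d}_partner",
                    partner,
                    GenomicInterval(chrom, p_start, p_start + size - 1),
                    copy_number,
                    klass,
                )
            )

    # low-probe events inside the sparse window: comfortably above the
    # size floor even after jitter, but only a handful of probes
    sp_cursor = sp_start + 200_000
    for i in range(config.n_low_probe):
        size = int(rng.integers(45_000, 60_000))
        interval = GenomicInterval(sp_chrom, sp_cursor, sp_cursor + size - 1)
        sp_cursor += size + 300_000
        events.append(
            PlantedEvent(
                f"low_probe_{i:02d}",
                str(rng.choice(samples)),
                interval,
                int(rng.choice([1, 3])),
                "low_probe",
            )
        )
    return events


def _plant_sex_events(
    config: SyntheticCohortConfig, rng, samples: list, sample_sex: dict
) -> list:
    events = []
    females = [s for s in samples if sample_sex[s] == "F"]
    males = [s for s in samples if sample_sex[s] == "M"]
    if females:
        # X duplication in a female, clear of PAR/XTR
        size = int(rng.integers(80_000, 300_000))
        start = int(rng.integers(1_000_000, 3_000_000))
        events.append(
            PlantedEvent(
                "sex_candidate_00",
                str(rng.choice(females)),
                GenomicInterval("X", start, start + size - 1),
                3,
                "sex_candidate",
            )
        )
    if males:
        # diploid PAR span wrongly reported as a CNV record (copy 2):
        # the selection stage must discard it
        events.append(
            PlantedEvent(
                "par_diploid_00",
                str(rng.choice(males)),
                GenomicInterval("X", 40_000, 140_000),
                2,
                "par_diploid",
            )
        )
    return events


# ---------------------------------------------------------------------------
# pseudo-callers


def _confidence(rng, caller: str, below: bool) -> float:
    floor = 35.0 if caller == "partitionstyle" else 10.0
    if below:
        return float(np.round(rng.uniform(0.0, floor - 0.1), 1))
    return float(np.round(floor + rng.exponential(30.0), 1))


def _emit_calls(
    config: SyntheticCohortConfig,
    rng,
    events: list,
    positions: dict,
    samples: list,
) -> tuple[list, list]:
    """Run both pseudo-callers over the planted events plus noise calls."""
    penn: list[CnvCall] = []
    partition: list[CnvCall] = []

    def jittered(iv: GenomicInterval) -> GenomicInterval:
        ds = int(rng.normal(0, config.jitter_sd_bp))
        de = int(rng.normal(0, config.jitter_sd_bp))
        start = max(1, iv.start + ds)
        end = max(start + 1_000, iv.end + de)
        return GenomicInterval(iv.chrom, start, end)

    def build(sample, iv, cn, caller) -> Optional[CnvCall]:
        n_probes = _count_probes(positions, iv)
        if n_probes < 1:
            return None
        below = rng.random() < config.subthreshold_conf_prob
        return CnvCall(
            sample=sample,
            interval=iv,
            copy_number=cn,
            n_probes=n_probes,
            confidence=_confidence(rng, caller, below),
            caller=caller,
            region_class=SYNTHETIC_REGIONS.classify(iv),
        )

    for ev in events:
        sex_chrom = ev.interval.chrom in ("X", "Y")
        callers = ("partitionstyle",) if sex_chrom else ("pennstyle", "partitionstyle")
        for caller in callers:
            if ev.klass != "par_diploid" and rng.random() < config.miss_prob:
                continue
            iv = jittered(ev.interval) if ev.klass != "par_diploid" else ev.interval
            if rng.random() < config.split_prob and iv.size_bp > 30_000:
                cut = iv.start + iv.size_bp // 2 + int(rng.integers(-5_000, 5_000))
                halves = [
                    GenomicInterval(iv.chrom, iv.start, cut),
                    GenomicInterval(iv.chrom, cut + 4_000, iv.end),
                ]
            else:
                halves = [iv]
            for part in halves:
                call = build(ev.sample, part, ev.copy_number, caller)
                if call is not None:
                    (penn if caller == "pennstyle" else partition).append(call)

    # false-positive noise calls: small (< 25 kb), uniformly scattered
    autosomes = [c for c in config.chromosome_sizes if c not in ("X", "Y")]
    for sample in samples:
        for caller, sink in (("pennstyle", penn), ("partitionstyle", partition)):
            for _ in range(rng.poisson(config.fp_per_sample)):
                chrom = str(rng.choice(autosomes))
                size = int(rng.integers(5_000, 20_000))
                start = int(rng.integers(1_000, config.chromosome_sizes[chrom] - size))
                call = build(
                    sample,
                    GenomicInterval(chrom, start, start + size - 1),
                    int(rng.choice([1, 3])),
                    caller,
                )
                if call is not None:
                    sink.append(call)

    key = lambda c: (c.sample, c.interval.chrom, c.interval.start, c.interval.end)
    return sorted(penn, key=key), sorted(partition, key=key)


# ---------------------------------------------------------------------------
# reference sets, transcriptome, gene sets


def _build_references(
    config: SyntheticCohortConfig, rng, events: list
) -> tuple[dict, ReferenceSet]:
    type_of = {1: "loss", 0: "loss", 3: "gain", 4: "gain"}

    def background(n: int) -> list:
        # confined to the reserved band of chromosome 1
        out = []
        for _ in range(n):
            size = int(rng.integers(20_000, 200_000))
            start = int(rng.integers(50_500_000, 58_000_000 - size))
            out.append(
                (
                    GenomicInterval("1", start, start + size - 1),
                    str(rng.choice(["loss", "gain", "both"])),
                )
            )
        return out

    common = [e for e in events if e.klass == "common_cnp"]
    common_entries = [
        (
            GenomicInterval(
                e.interval.chrom, max(1, e.interval.start - 5_000), e.interval.end + 5_000
            ),
            type_of[e.copy_number],
        )
        for e in common
    ]
    references = {
        "hapmap_cnp": ReferenceSet("hapmap_cnp", common_entries + background(15)),
        "chop_blocks": ReferenceSet("chop_blocks", common_entries + background(10)),
        "internal_controls": ReferenceSet(
            "internal_controls", common_entries + background(8)
        ),
        "unrelated_case_db": ReferenceSet("unrelated_case_db", background(8)),
    }
    dgv_entries = background(10)
    for e in events:
        if e.klass != "dgv_like":
            continue
        # two same-type catalogue entries, each covering ~80% of the event
        span = e.interval.size_bp
        for shift in (-span // 5, span // 5):
            start = max(1, e.interval.start + shift)
            dgv_entries.append(
                (
                    GenomicInterval(e.interval.chrom, start, start + span - 1),
                    type_of[e.copy_number],
                )
            )
    dgv = ReferenceSet("dgv", sorted(dgv_entries, key=lambda t: (t[0].chrom, t[0].start)))
    for ref in references.values():
        ref.entries.sort(key=lambda t: (t[0].chrom, t[0].start))
    return references, dgv


def _build_transcriptome(config: SyntheticCohortConfig, rng) -> tuple[list, list]:
    """A gene every ~250 kb on the autosomes (60 kb spans)."""
    from .models import TranscriptRecord

    transcripts = []
    universe = []
    gene_no = 0
    for chrom in ("1", "2"):
        size = config.chromosome_sizes[chrom]
        for start in range(200_000, size - 100_000, 250_000):
            gene_no += 1
            symbol = f"G{gene_no:05d}"
            universe.append(symbol)
            transcripts.append(
                TranscriptRecord(
                    gene=symbol,
                    interval=GenomicInterval(chrom, start, start + 60_000 - 1),
                    biotype="protein_coding",
                )
            )
    return transcripts, universe


def _build_gene_sets(
    config: SyntheticCohortConfig,
    rng,
    universe: list,
    events: list,
    transcripts: list,
) -> tuple[dict, str]:
    """Random gene sets plus one planted set drawn from >= 3 rare events."""
    from .annotate import index_transcripts, intersect_transcripts

    index = index_transcripts(transcripts)
    rare = [e for e in events if e.klass == "rare_candidate"]
    planted_genes: list[str] = []
    for e in rare:
        planted_genes.extend(intersect_transcripts(e.interval, index))
    planted_genes = sorted(set(planted_genes))
    library: dict[str, frozenset] = {}
    lo, hi = config.gene_set_size
    for i in range(config.n_gene_sets):
        n = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=min(n, len(universe)), replace=False)
        library[f"SET_{i:03d}"] = frozenset(universe[j] for j in members)
    planted_name = "PLANTED_PATHWAY"
    filler = [g for g in universe if g not in planted_genes]
    pad = rng.choice(len(filler), size=max(0, 10 - len(planted_genes)), replace=False)
    library[planted_name] = frozenset(planted_genes) | frozenset(filler[j] for j in pad)
    return library, planted_name


# ---------------------------------------------------------------------------
# probe intensity tables


def _probe_tables(
    config: SyntheticCohortConfig,
    rng,
    events: list,
    positions: dict,
    samples: list,
    sample_sex: dict,
) -> dict:
    """Per-sample probe records around planted events plus one ROH region.

    Artifact-class events get diploid-looking intensities (mean LRR ~0)
    so the review stage can catch them; all other events shift LRR by
    the state mean. The first case carries a 2 Mb run of homozygosity
    on chromosome 1 at 58-60 Mb (outside all planted-event lanes).
    """
    windows: dict[str, list] = {s: [] for s in samples}
    for ev in events:
        flank = 20_000
        windows[ev.sample].append(
            (
                ev.interval.chrom,
                max(1, ev.interval.start - flank),
                ev.interval.end + flank,
                ev,
            )
        )
    roh_sample = samples[0]
    roh_span = ("1", 58_000_000, 60_000_000)

    tables: dict[str, list] = {}
    for sample in samples:
        records: list[ProbeRecord] = []
        spans = windows[sample] + (
            [(roh_span[0], roh_span[1], roh_span[2], None)]
            if sample == roh_sample
            else []
        )
        for chrom, lo, hi, ev in spans:
            pos = positions[chrom]
            sel = pos[(pos >= lo) & (pos <= hi)]
            for p in sel:
                in_event = ev is not None and ev.interval.contains(int(p))
                cn = ev.copy_number if in_event else 2
                if ev is not None and ev.klass == "artifact":
                    cn = 2  # intensities do not support the planted call
                if ev is None and sample == roh_sample and chrom == "1":
                    genotype = "AA" if rng.random() < 0.5 else "BB"
                    baf = 0.0 if genotype == "AA" else 1.0
                    lrr = rng.normal(0.0, config.lrr_sd)
                else:
                    genotype, baf = _genotype_and_baf(rng, cn)
                    mean = (
                        config.lrr_loss_mean
                        if cn < 2
                        else (config.lrr_gain_mean if cn > 2 else 0.0)
                    )
                    lrr = rng.normal(mean, config.lrr_sd)
                records.append(
                    ProbeRecord(
                        marker=f"m_{chrom}_{int(p)}",
                        chrom=chrom,
                        position=int(p),
                        genotype=genotype,
                        baf=float(np.clip(baf + rng.normal(0, 0.02), 0, 1)),
                        lrr=float(np.round(lrr, 4)),
                    )
                )
        records.sort(key=lambda r: (r.chrom, r.position))
        tables[sample] = records
    return tables


def _genotype_and_baf(rng, cn: int) -> tuple[str, float]:
    p = rng.uniform(0.2, 0.8)
    if rng.random() < 0.002:
        return "NC", rng.uniform(0, 1)
    if cn <= 1:
        g = "AA" if rng.random() < p else "BB"
        return g, 0.0 if g == "AA" else 1.0
    u = rng.random()
    if u < p * p:
        return "AA", 0.0
    if u < p * p + 2 * p * (1 - p):
        # heterozygous; BAF splits off 0.5 for copy-number 3
        return "AB", 0.5 if cn == 2 else (0.33 if rng.random() < 0.5 else 0.67)
    return "BB", 1.0


# ---------------------------------------------------------------------------
# variants


def generate_variants(
    config: SyntheticCohortConfig, rng=None, samples: Optional[list] = None
) -> list:
    """Sequence variants with binomial read counts and planted classes.

    True heterozygotes draw alternate reads from Binomial(depth, 0.5),
    systematic artifacts from Binomial(depth, 0.1); a few common
    variants carry population frequencies above the rarity ceiling.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if samples is None:
        samples = [f"S{i:03d}" for i in range(1, config.n_cases + 1)]
    genes_known = ["NKX2-5", "GATA4", "MYH7"]
    genes_candidate = ["MYH6", "TTN", "TCAP", "JUP", "CORIN", "TBX5", "SMARCA4"]
    out: list[PlantedVariant] = []

    def depth() -> int:
        return max(30, int(rng.poisson(config.mean_depth)))

    def make(klass: str, i: int) -> PlantedVariant:
        d = depth()
        if klass == "artifact":
            alt = int(rng.binomial(d, 0.1))
        else:
            alt = int(rng.binomial(d, 0.5))
        tier = "known_ea_gene" if rng.random() < 0.4 else "candidate_gene"
        gene = str(rng.choice(genes_known if tier == "known_ea_gene" else genes_candidate))
        if klass == "common":
            af = float(np.round(rng.uniform(0.01, 0.2), 4))
        else:
            af = None if rng.random() < 0.5 else float(np.round(rng.uniform(1e-6, 1e-3), 8))
        return PlantedVariant(
            variant=SequenceVariant(
                sample=str(rng.choice(samples)),
                chrom=str(rng.choice(["2", "5", "14", "17"])),
                pos=int(rng.integers(1_000_000, 40_000_000)),
                ref="A",
                alt="G",
                gene=gene,
                ref_reads=d - alt,
                alt_reads=alt,
                population_af=af,
                tier=tier,
                impact_flag=True,
                zygosity_call="het",
            ),
            klass=klass,
        )

    i = 0
    for klass, n in (
        ("true_het", config.n_true_het),
        ("artifact", config.n_artifact_variants),
        ("common", config.n_common_variants),
    ):
        for _ in range(n):
            out.append(make(klass, i))
            i += 1
    out.sort(key=lambda pv: (pv.variant.sample, pv.variant.chrom, pv.variant.pos))
    return out


# ---------------------------------------------------------------------------
# top level


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a complete in-memory cohort bundle from the config seed."""
    for klass_count in ("n_rare", "n_common", "n_dgv"):
        if getattr(config, klass_count) < 0:
            raise ValueError(f"{klass_count} must be nonnegative")
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i:03d}" for i in range(1, config.n_cases + 1)]
    controls = [f"K{i:03d}" for i in range(1, config.n_controls + 1)]
    sample_sex = {
        s: ("F" if i % 2 else "M") for i, s in enumerate(samples + controls)
    }
    positions = _probe_positions(config)

    events = _place_events(config, rng, samples)
    if config.include_sex_events:
        events.extend(_plant_sex_events(config, rng, samples, sample_sex))
    for ev in events:
        chrom_size = config.chromosome_sizes.get(ev.interval.chrom)
        if chrom_size is None or ev.interval.end > chrom_size:
            raise ValueError(f"planted event {ev.event_id} outside chromosome bounds")

    penn, partition = _emit_calls(config, rng, events, positions, samples)
    references, dgv = _build_references(config, rng, events)
    transcripts, universe = _build_transcriptome(config, rng)
    library, planted_set = _build_gene_sets(config, rng, universe, events, transcripts)
    probes_by_sample = _probe_tables(config, rng, events, positions, samples, sample_sex)
    variants = generate_variants(config, rng, samples)

    # candidate-gene list: half of the genes inside rare events
    from .annotate import index_transcripts, intersect_transcripts

    index = index_transcripts(transcripts)
    rare_genes = sorted(
        {
            g
            for e in events
            if e.klass == "rare_candidate"
            for g in intersect_transcripts(e.interval, index)
        }
    )
    candidate_gene_list = frozenset(rare_genes[::2])

    return SyntheticCohort(
        config=config,
        samples=samples,
        sample_sex=sample_sex,
        probe_positions=positions,
        penn_calls=penn,
        partition_calls=partition,
        references=references,
        dgv=dgv,
        transcripts=transcripts,
        gene_universe=universe,
        gene_set_library=library,
        planted_set_name=planted_set,
        events=events,
        variants=variants,
        probes_by_sample=probes_by_sample,
        candidate_gene_list=candidate_gene_list,
    )


def write_bundle(cohort: SyntheticCohort, outdir) -> dict:
    """Serialize a cohort to the pipeline's input formats; return manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_cnv_calls(cohort.penn_calls, outdir / "calls_penn.rawcnv", "pennstyle")
    io_formats.write_cnv_calls(
        cohort.partition_calls, outdir / "calls_partition.tsv", "partitionstyle"
    )
    for name, ref in sorted(cohort.references.items()):
        io_formats.write_reference_cnv_set(ref, outdir / f"ref_{name}.tsv")
    io_formats.write_reference_cnv_set(cohort.dgv, outdir / "ref_dgv.tsv")
    io_formats.write_transcript_bed(cohort.transcripts, outdir / "transcripts.bed")
    io_formats.write_gene_set_library(cohort.gene_set_library, outdir / "gene_sets.gmt")
    io_formats.write_symbol_list(cohort.candidate_gene_list, outdir / "candidate_genes.txt")
    io_formats.write_variant_table(
        [pv.variant for pv in cohort.variants], outdir / "variants.tsv"
    )
    for sample in cohort.samples:
        io_formats.write_probe_table(
            cohort.probes_by_sample[sample], outdir / f"probes_{sample}.tsv"
        )
    with open(outdir / "sample_sex.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample\tsex\n")
        for s in sorted(cohort.sample_sex):
            fh.write(f"{s}\t{cohort.sample_sex[s]}\n")
    with open(outdir / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("event_id\tsample\tchrom\tstart\tend\tcopy_number\tclass\texpected_fate\n")
        for ev in sorted(cohort.events, key=lambda e: e.event_id):
            iv = ev.interval
            fh.write(
                f"{ev.event_id}\t{ev.sample}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{ev.copy_number}\t{ev.klass}\t{ev.expected_fate}\n"
            )
    manifest = {
        "seed": cohort.config.seed,
        "config_hash": cohort.config.config_hash(),
        "n_cases": cohort.config.n_cases,
        "n_events": len(cohort.events),
        "n_penn_calls": len(cohort.penn_calls),
        "n_partition_calls": len(cohort.partition_calls),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
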