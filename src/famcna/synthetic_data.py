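"""Synthetic SNP-array and expression cohorts with recorded ground truth.

This module emulates the data a familial breast-tumour profiling study works
from, at desk scale:

* a marker map (ordered SNP markers with GC fraction and restriction-fragment
  length) over chromosomes 1-22 and X;
* a normal reference cohort of diploid females, used as the copy-number
  baseline;
* tumour cohorts in four mutation classes (CHEK2, BRCAX, BRCA1, BRCA2) with
  planted copy-number events and loss of heterozygosity, observed through a
  mixture of tumour cells (fraction = purity) and diploid non-tumour cells,
  part of which are infiltrating lymphocytes (TILs);
* a log2-scale expression matrix whose immune-signature genes track the
  lymphocyte fraction, whose intrinsic genes separate luminal from basal-like
  tumours, and which carries a small set of planted class differences.

Every planted quantity (events, purity, TIL fraction, gene roles) is recorded
so that downstream callers can be scored against the truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GenerationError

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

#: fraction of a chromosome's markers assigned to the p arm
ARM_FRACTION = 0.45

MUTATION_CLASSES = ("CHEK2", "BRCAX", "BRCA1", "BRCA2")
SUBTYPES = ("luminal", "basal")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEvent:
    """A contiguous copy-number event in the tumour-cell population.

    ``start``/``end`` are chromosome-local marker indices, 0-based half-open.
    ``total_copies`` is the tumour-cell copy number over the run and
    ``b_copies`` the number of B-allele copies carried at markers that are
    heterozygous in the germ line.  LOH is implied iff ``b_copies`` is 0 or
    ``total_copies``.
    """

    chromosome: str
    start: int
    end: int
    total_copies: int
    b_copies: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigurationError(f"event {self.name!r} spans no marker")
        if self.total_copies < 0:
            raise ConfigurationError("total_copies must be non-negative")
        if not 0 <= self.b_copies <= self.total_copies:
            raise ConfigurationError("b_copies must be in [0, total_copies]")

    @property
    def implies_loh(self) -> bool:
        return self.b_copies in (0, self.total_copies)


@dataclass
class SampleTruth:
    """Ground truth for one simulated tumour sample."""

    sample_id: str
    mutation_class: str
    subtype: str
    purity: float
    til_fraction: float  # lymphocyte fraction of the non-tumour compartment
    events: list[PlantedEvent] = field(default_factory=list)


@dataclass
class ExpressionConfig:
    """Expression-matrix block of the simulation configuration.

    ``signature_effect_sd_units`` scales the immune-gene shift: a sample with
    TIL fraction ``t`` has its signature genes shifted by
    ``signature_effect_sd_units * t * expr_noise_sd`` log2 units.  The
    default TIL strata have mean fractions ~0.25 (low) and ~0.75 (high), so
    the default of 3.0 realises a 1.5-SD signature contrast between the
    strata.  ``de_log2_fc`` is the planted log2 fold-change of the
    differential genes (higher in CHEK2), 1.26 log2 units = linear
    fold-change 2.4.
    """

    n_genes: int = 2000
    n_signature_genes: int = 100
    signature_effect_sd_units: float = 3.0
    n_subtype_genes: int = 100
    subtype_log2_separation: float = 1.0
    n_de_genes: int = 6
    de_log2_fc: float = 1.26
    expr_noise_sd: float = 0.25


@dataclass
class GroupSizes:
    """Cohort composition: tumour counts per mutation class and TIL stratum.

    Defaults give 14 low-TIL + 3 high-TIL CHEK2 and 34 low-TIL + 15 high-TIL
    BRCAX luminal tumours, plus BRCA1/BRCA2 tumours filling a 120-sample
    cohort.
    """

    chek2_low: int = 14
    chek2_high: int = 3
    brcax_low: int = 34
    brcax_high: int = 15
    brca1: int = 47
    brca2: int = 7

    @property
    def total(self) -> int:
        return (self.chek2_low + self.chek2_high + self.brcax_low
                + self.brcax_high + self.brca1 + self.brca2)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-scale defaults."""

    n_markers_per_chromosome: int = 500
    n_reference_samples: int = 90
    groups: GroupSizes = field(default_factory=GroupSizes)
    lrr_noise_sd: float = 0.15
    baf_noise_sd: float = 0.03
    het_fraction: float = 0.30
    #: sd of the per-sample GC-wave coefficient (log2 units per GC unit)
    gc_wave_sd: float = 0.2
    #: sd of the per-sample fragment-length coefficient (per log-bp)
    fragment_wave_sd: float = 0.1
    #: truth label "high TIL" means til_fraction > this cutoff
    til_high_cutoff: float = 0.5
    #: sd of the pathology-style observed TIL percentage around 100*truth
    til_percent_noise_sd: float = 5.0
    #: disable all planted events (pure-diploid tumour cohort) when False
    plant_events: bool = True
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_markers_per_chromosome <= 0:
            raise ConfigurationError("n_markers_per_chromosome must be > 0")
        if self.n_reference_samples < 2:
            raise ConfigurationError("need at least 2 reference samples")
        if self.groups.total <= 0:
            raise ConfigurationError("cohort is empty")
        for name in ("lrr_noise_sd", "baf_noise_sd", "gc_wave_sd",
                     "fragment_wave_sd", "til_percent_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ConfigurationError("het_fraction must be in [0, 1]")
        e = self.expression
        if min(e.n_genes, e.n_signature_genes, e.n_de_genes,
               e.n_subtype_genes) < 0 or e.n_genes == 0:
            raise ConfigurationError("gene counts must be positive")
        if e.n_signature_genes + e.n_de_genes + e.n_subtype_genes > e.n_genes:
            raise ConfigurationError(
                "signature + subtype + DE genes exceed n_genes")
        if e.expr_noise_sd < 0:
            raise ConfigurationError("expr_noise_sd must be >= 0")


@dataclass
class SimulatedCohort:
    """Generator output: signal matrices, reference cohort and full truth."""

    marker_map: pd.DataFrame
    tumor_copy: pd.DataFrame      # linear copy-scale signal, markers x samples
    tumor_baf: pd.DataFrame
    reference_copy: pd.DataFrame
    reference_baf: pd.DataFrame
    truth: dict[str, SampleTruth]
    metadata: pd.DataFrame        # indexed by sample_id


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent, reproducible substream for one generation stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------

def simulate_marker_map(config: SimulationConfig) -> pd.DataFrame:
    """Draw an ordered marker map over chromosomes 1-22 and X.

    Positions are strictly increasing within each chromosome; GC fraction is
    uniform on [0.3, 0.7] and fragment length uniform on [100, 2000] bp.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_markers_per_chromosome
    frames = []
    for chrom in CHROMOSOMES:
        gaps = rng.integers(1_000, 50_000, size=n)
        positions = 10_000 + np.cumsum(gaps)
        frames.append(pd.DataFrame({
            "marker_id": [f"SNP{chrom}_{i:05d}" for i in range(n)],
            "chromosome": chrom,
            "position": positions,
            "gc_fraction": rng.uniform(0.3, 0.7, size=n),
            "fragment_length": rng.integers(100, 2_001, size=n),
        }))
    mm = pd.concat(frames, ignore_index=True)
    validate_marker_map(mm)
    return mm


def validate_marker_map(marker_map: pd.DataFrame) -> None:
    """Enforce the marker-map invariants; raises ConfigurationError."""
    required = {"marker_id", "chromosome", "position", "gc_fraction",
                "fragment_length"}
    missing = required - set(marker_map.columns)
    if missing:
        raise ConfigurationError(f"marker map lacks columns {sorted(missing)}")
    if marker_map["marker_id"].duplicated().any():
        raise ConfigurationError("marker ids are not unique")
    for _, grp in marker_map.groupby("chromosome", sort=False):
        if not grp["position"].is_monotonic_increasing or \
                grp["position"].duplicated().any():
            raise ConfigurationError(
                "positions must be strictly increasing within chromosomes")
    gc = marker_map["gc_fraction"]
    if ((gc < 0) | (gc > 1)).any():
        raise ConfigurationError("gc_fraction outside [0, 1]")
    if (marker_map["fragment_length"] <= 0).any():
        raise ConfigurationError("fragment_length must be positive")


# ---------------------------------------------------------------------------
# admixture mixing
# ---------------------------------------------------------------------------

def mix_copy_number(purity: float, tumor_copies: int | float) -> float:
    """Population-average copy number of a locus under diploid admixture.

    ``purity * tumor_copies + (1 - purity) * 2``; the noise-free log2 ratio of
    the locus is ``log2(result / 2)``.
    """
    if not 0.0 <= purity <= 1.0:
        raise ConfigurationError("purity must be in [0, 1]")
    if tumor_copies < 0:
        raise ConfigurationError("tumor_copies must be non-negative")
    return purity * tumor_copies + (1.0 - purity) * 2.0


def mix_baf(purity: float, tumor_total: int, tumor_b: int,
            germline_b_of_2: int,
            rng: np.random.Generator | None = None) -> float:
    """B-allele frequency of a locus under diploid admixture.

    ``(purity*tumor_b + (1-purity)*germline_b) / (purity*tumor_total +
    (1-purity)*2)``.  When the denominator is zero (pure tumour, homozygous
    deletion) there is no DNA at the locus and the observed BAF is resampled
    uniformly on [0, 1].
    """
    if not 0.0 <= purity <= 1.0:
        raise ConfigurationError("purity must be in [0, 1]")
    if not 0 <= tumor_b <= tumor_total:
        raise ConfigurationError("tumor_b must be in [0, tumor_total]")
    if germline_b_of_2 not in (0, 1, 2):
        raise ConfigurationError("germline_b_of_2 must be 0, 1 or 2")
    denom = purity * tumor_total + (1.0 - purity) * 2.0
    if denom == 0.0:
        if rng is None:
            rng = np.random.default_rng()
        return float(rng.uniform())
    return (purity * tumor_b + (1.0 - purity) * germline_b_of_2) / denom


# ---------------------------------------------------------------------------
# event plan
# ---------------------------------------------------------------------------

def _event(name: str, chrom: str, lo: float, hi: float, total: int, b: int,
           n_markers: int) -> PlantedEvent:
    start = int(round(lo * n_markers))
    end = int(round(hi * n_markers))
    return PlantedEvent(chrom, start, end, total, b, name=name)


def _event_catalog(n_markers: int) -> dict[str, PlantedEvent]:
    """Named whole-arm / focal events used by the default cohort plan."""
    a = ARM_FRACTION
    spec = [
        # classic luminal profile: 1q+, 8q+, 16p+ gains; 8p-, 16q- losses
        ("gain_1q", "1", a, 1.0, 3, 2),
        ("gain_8q", "8", a, 1.0, 3, 2),
        ("gain_16p", "16", 0.0, a, 3, 2),
        ("loss_8p", "8", 0.0, a, 1, 0),
        ("loss_16q", "16", a, 1.0, 1, 0),
        # basal-like profile
        ("loss_5q", "5", a, 1.0, 1, 0),
        ("gain_3q", "3", a, 1.0, 3, 2),
        # class-differential events
        ("loss_1p", "1", 0.0, a, 1, 0),
        ("loss_22", "22", 0.0, 1.0, 1, 0),
        # focal high-level amplification with allelic imbalance (ERBB2-like)
        ("amp_17q_focal", "17", 0.60, 0.70, 10, 9),
    ]
    return {name: _event(name, c, lo, hi, t, b, n_markers)
            for name, c, lo, hi, t, b in spec}


ARCHETYPE_EVENTS = ("gain_1q", "gain_8q", "gain_16p", "loss_8p", "loss_16q")
BASAL_EVENTS = ("loss_5q", "gain_3q")

#: per-class planting plan for low-TIL tumours: exact counts out of the
#: low-TIL class size (chosen samples drawn at random).
LOW_TIL_CLASS_COUNTS: dict[str, dict[str, float]] = {
    "CHEK2": {"loss_1p": 6 / 14, "loss_22": 7 / 14, "amp_17q_focal": 6 / 14},
    "BRCAX": {"loss_1p": 2 / 34, "loss_22": 8 / 34},
    "BRCA1": {"loss_22": 0.25},
    "BRCA2": {"loss_22": 0.25},
}
#: same events as independent per-sample probabilities for high-TIL tumours
HIGH_TIL_CLASS_PROBS = LOW_TIL_CLASS_COUNTS

ARCHETYPE_PROB_LOW = 0.5
ARCHETYPE_PROB_HIGH = 0.3
BASAL_EVENT_PROB = 0.6


def _check_no_overlap(events: list[PlantedEvent]) -> None:
    by_chrom: dict[str, list[PlantedEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chromosome, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for left, right in zip(evs, evs[1:]):
            if right.start < left.end:
                raise GenerationError(
                    f"overlapping events {left.name!r} and {right.name!r} "
                    f"on chromosome {chrom}")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _sample_plan(config: SimulationConfig,
                 rng: np.random.Generator) -> list[SampleTruth]:
    """Lay out sample ids, classes, subtypes, TIL strata, purity and events."""
    g = config.groups
    rows: list[tuple[str, bool]] = []          # (class, high_til)
    rows += [("CHEK2", False)] * g.chek2_low + [("CHEK2", True)] * g.chek2_high
    rows += [("BRCAX", False)] * g.brcax_low + [("BRCAX", True)] * g.brcax_high
    # BRCA1 tumours are mostly basal-like and TIL-rich; BRCA2 mostly luminal
    n_b1_high = int(round(0.6 * g.brca1))
    b1_high = np.zeros(g.brca1, dtype=bool)
    b1_high[rng.choice(g.brca1, size=n_b1_high, replace=False)] = True
    rows += [("BRCA1", bool(h)) for h in b1_high]
    n_b2_high = int(round(0.3 * g.brca2))
    b2_high = np.zeros(g.brca2, dtype=bool)
    if g.brca2:
        b2_high[rng.choice(g.brca2, size=n_b2_high, replace=False)] = True
    rows += [("BRCA2", bool(h)) for h in b2_high]

    catalog = _event_catalog(config.n_markers_per_chromosome)
    truths: list[SampleTruth] = []
    counters: dict[str, int] = {}
    for cls, high in rows:
        counters[cls] = counters.get(cls, 0) + 1
        sid = f"{cls}_{counters[cls]:03d}"
        if cls == "BRCA1":
            subtype = "basal" if rng.uniform() < 0.8 else "luminal"
        else:
            subtype = "luminal"
        til = rng.uniform(0.55, 0.95) if high else rng.uniform(0.05, 0.45)
        purity = rng.uniform(0.2, 0.5) if high else rng.uniform(0.5, 0.9)
        truths.append(SampleTruth(sid, cls, subtype, purity, til, []))

    if not config.plant_events:
        return truths

    # background profile events
    for t in truths:
        high = t.til_fraction > config.til_high_cutoff
        if t.subtype == "luminal":
            p = ARCHETYPE_PROB_HIGH if high else ARCHETYPE_PROB_LOW
            if rng.uniform() < p:
                t.events.extend(catalog[name] for name in ARCHETYPE_EVENTS)
        else:
            t.events.extend(catalog[name] for name in BASAL_EVENTS
                            if rng.uniform() < BASAL_EVENT_PROB)

    # class-differential events: exact counts within each low-TIL class,
    # independent probabilities for high-TIL samples
    for cls in MUTATION_CLASSES:
        low = [t for t in truths if t.mutation_class == cls
               and t.til_fraction <= config.til_high_cutoff]
        for name, frac in LOW_TIL_CLASS_COUNTS.get(cls, {}).items():
            k = int(round(frac * len(low)))
            if k and low:
                for idx in rng.choice(len(low), size=min(k, len(low)),
                                      replace=False):
                    low[idx].events.append(catalog[name])
        high = [t for t in truths if t.mutation_class == cls
                and t.til_fraction > config.til_high_cutoff]
        for t in high:
            for name, p in HIGH_TIL_CLASS_PROBS.get(cls, {}).items():
                if rng.uniform() < p:
                    t.events.append(catalog[name])

    for t in truths:
        _check_no_overlap(t.events)
    return truths


def _genome_arrays(truth: SampleTruth,
                   marker_map: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (total_copies, b_copies) arrays over the whole genome."""
    n = len(marker_map)
    total = np.full(n, 2, dtype=np.int64)
    bcop = np.full(n, 1, dtype=np.int64)   # B copies given germline het
    offsets = {}
    off = 0
    for chrom, grp in marker_map.groupby("chromosome", sort=False):
        offsets[chrom] = off
        off += len(grp)
    for ev in truth.events:
        o = offsets[ev.chromosome]
        total[o + ev.start:o + ev.end] = ev.total_copies
        bcop[o + ev.start:o + ev.end] = ev.b_copies
    return total, bcop


def truth_copy_number(truth: SampleTruth, marker_map: pd.DataFrame
                      ) -> np.ndarray:
    """Per-marker tumour-cell total copy number implied by the truth."""
    return _genome_arrays(truth, marker_map)[0]


def _mix_baf_array(purity: float, total: np.ndarray, b_tumor: np.ndarray,
                   germline_b: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    denom = purity * total + (1.0 - purity) * 2.0
    num = purity * b_tumor + (1.0 - purity) * germline_b
    out = np.empty(total.shape, dtype=float)
    zero = denom == 0.0
    np.divide(num, denom, out=out, where=~zero)
    if zero.any():
        out[zero] = rng.uniform(size=int(zero.sum()))
    return out


def _observed_copy_signal(mixed: np.ndarray, marker_map: pd.DataFrame,
                          config: SimulationConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Linear copy-scale signal: admixed copies times wave and noise terms."""
    gc_c = marker_map["gc_fraction"].to_numpy()
    gc_c = gc_c - gc_c.mean()
    lfl = np.log(marker_map["fragment_length"].to_numpy(dtype=float))
    lfl_c = lfl - lfl.mean()
    wave = (rng.normal(0.0, config.gc_wave_sd) * gc_c
            + rng.normal(0.0, config.fragment_wave_sd) * lfl_c)
    noise = rng.normal(0.0, config.lrr_noise_sd, len(marker_map))
    return np.maximum(mixed, 1e-3) * np.exp2(wave + noise)


def synthesize_tumor_signal(truth: SampleTruth, marker_map: pd.DataFrame,
                            config: SimulationConfig,
                            rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed (copy_signal, baf, germline_genotype) for one tumour sample.

    The genotype vector holds germline B-allele counts in {0, 1, 2}; tumour
    B copies at het markers follow the planted event's ``b_copies``.
    """
    n_mark = len(marker_map)
    het = config.het_fraction
    geno = rng.choice(3, size=n_mark,
                      p=[(1 - het) / 2, het, (1 - het) / 2])
    total, bcop = _genome_arrays(truth, marker_map)
    # tumour-cell B copies by germline genotype: hom-A stays 0, het carries
    # the event's b_copies, hom-B carries all copies
    b_tumor = np.where(geno == 0, 0, np.where(geno == 1, bcop, total))
    mixed = truth.purity * total + (1.0 - truth.purity) * 2.0
    copy_signal = _observed_copy_signal(mixed, marker_map, config, rng)
    baf = _mix_baf_array(truth.purity, total.astype(float),
                         b_tumor.astype(float), geno.astype(float), rng)
    baf = np.clip(baf + rng.normal(0.0, config.baf_noise_sd, n_mark), 0, 1)
    return copy_signal, baf, geno


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the reference cohort and the tumour cohort with truth.

    Reference samples are diploid with Gaussian log2-ratio noise and BAF
    clustered at {0, 0.5, 1} by germline genotype.  Tumour samples observe
    every planted event through the purity/TIL admixture model, plus the same
    noise and per-sample GC / fragment-length waves.
    """
    config.validate()
    marker_map = simulate_marker_map(config)
    rng = _rng(config, 1)
    truths = _sample_plan(config, rng)

    n_mark = len(marker_map)
    het = config.het_fraction
    geno_p = [(1 - het) / 2, het, (1 - het) / 2]

    # reference cohort (diploid females)
    ref_ids = [f"REF_{i:03d}" for i in range(config.n_reference_samples)]
    ref_copy = np.empty((n_mark, len(ref_ids)))
    ref_baf = np.empty_like(ref_copy)
    for j in range(len(ref_ids)):
        geno = rng.choice(3, size=n_mark, p=geno_p)
        ref_copy[:, j] = _observed_copy_signal(
            np.full(n_mark, 2.0), marker_map, config, rng)
        ref_baf[:, j] = np.clip(
            geno / 2.0 + rng.normal(0.0, config.baf_noise_sd, n_mark), 0, 1)

    # tumour cohort
    tum_ids = [t.sample_id for t in truths]
    tum_copy = np.empty((n_mark, len(tum_ids)))
    tum_baf = np.empty_like(tum_copy)
    for j, t in enumerate(truths):
        tum_copy[:, j], tum_baf[:, j], _ = synthesize_tumor_signal(
            t, marker_map, config, rng)

    idx = marker_map["marker_id"]
    meta = pd.DataFrame({
        "sample_id": tum_ids,
        "mutation_class": [t.mutation_class for t in truths],
        "subtype": [t.subtype for t in truths],
        "purity": [t.purity for t in truths],
        "til_fraction": [t.til_fraction for t in truths],
        "high_til": [t.til_fraction > config.til_high_cutoff for t in truths],
        "observed_til_percent": np.clip(
            np.array([t.til_fraction for t in truths]) * 100.0
            + rng.normal(0.0, config.til_percent_noise_sd, len(truths)),
            0.0, 100.0),
    }).set_index("sample_id")

    return SimulatedCohort(
        marker_map=marker_map,
        tumor_copy=pd.DataFrame(tum_copy, index=idx, columns=tum_ids),
        tumor_baf=pd.DataFrame(tum_baf, index=idx, columns=tum_ids),
        reference_copy=pd.DataFrame(ref_copy, index=idx, columns=ref_ids),
        reference_baf=pd.DataFrame(ref_baf, index=idx, columns=ref_ids),
        truth={t.sample_id: t for t in truths},
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig,
                        truth: dict[str, SampleTruth] | list[SampleTruth],
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a log2-scale genes x samples expression matrix.

    Returns ``(matrix, gene_info)`` where ``gene_info`` records each gene's
    role (``signature`` / ``subtype`` / ``de`` / ``null``), its direction of
    association with TIL fraction, and the luminal/basal archetype means of
    the intrinsic (subtype) genes.

    Immune-signature genes are shifted by
    ``signature_effect_sd_units * til_fraction * expr_noise_sd``; subtype
    genes split samples by intrinsic subtype; DE genes are shifted up in
    CHEK2 tumours by ``de_log2_fc``.
    """
    config.validate()
    truths = list(truth.values()) if isinstance(truth, dict) else list(truth)
    if not truths:
        raise ConfigurationError("truth is empty")
    e = config.expression
    rng = _rng(config, 2)

    sample_ids = [t.sample_id for t in truths]
    til = np.array([t.til_fraction for t in truths])
    luminal = np.array([t.subtype == "luminal" for t in truths])
    chek2 = np.array([t.mutation_class == "CHEK2" for t in truths])

    n_sig, n_sub, n_de = e.n_signature_genes, e.n_subtype_genes, e.n_de_genes
    roles = np.array(["signature"] * n_sig + ["subtype"] * n_sub
                     + ["de"] * n_de
                     + ["null"] * (e.n_genes - n_sig - n_sub - n_de))
    gene_ids = [f"G{i:05d}_{r}" for i, r in enumerate(roles)]

    base = rng.normal(7.0, 1.0, e.n_genes)
    x = base[:, None] + rng.normal(0.0, e.expr_noise_sd,
                                   (e.n_genes, len(truths)))

    # per-gene effect sizes vary (uniform 0.5-1.5x the nominal effect) and
    # half the signature genes move down with infiltration; correlation-based
    # clustering of samples relies on this gene-to-gene heterogeneity -- a
    # signature whose genes all shift identically is invisible to a
    # correlation distance, which centers each sample profile
    til_effect = rng.uniform(0.5, 1.5, n_sig)
    til_direction = np.where(np.arange(n_sig) % 2 == 0, 1.0, -1.0)
    shift_sig = e.signature_effect_sd_units * e.expr_noise_sd
    x[:n_sig, :] += (shift_sig * (til_effect * til_direction)[:, None]
                     * til[None, :])

    # intrinsic genes: first half up in luminal, second half up in basal
    sep = e.subtype_log2_separation / 2.0
    sub_sign = np.where(np.arange(n_sub) < n_sub // 2, 1.0, -1.0)
    lum_term = np.where(luminal, 1.0, -1.0)
    x[n_sig:n_sig + n_sub, :] += sep * sub_sign[:, None] * lum_term[None, :]

    x[n_sig + n_sub:n_sig + n_sub + n_de, :] += e.de_log2_fc * chek2[None, :]

    gene_info = pd.DataFrame({
        "gene_id": gene_ids,
        "role": roles,
        "til_direction": np.concatenate(
            [til_direction, np.zeros(e.n_genes - n_sig)]).astype(int),
        "til_effect": np.concatenate(
            [til_effect, np.zeros(e.n_genes - n_sig)]),
        "luminal_mean": base,
        "basal_mean": base,
    }).set_index("gene_id")
    sub_slice = slice(n_sig, n_sig + n_sub)
    gene_info.iloc[sub_slice, gene_info.columns.get_loc("luminal_mean")] = \
        base[sub_slice] + sep * sub_sign
    gene_info.iloc[sub_slice, gene_info.columns.get_loc("basal_mean")] = \
        base[sub_slice] - sep * sub_sign

    matrix = pd.DataFrame(x, index=pd.Index(gene_ids, name="gene_id"),
                          columns=sample_ids)
    return matrix, gene_info
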