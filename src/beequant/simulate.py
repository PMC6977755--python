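"""Synthetic communities, marker references, and amplicon reads.

The generator emulates a two-year blue-vane-trap survey of grassland bee
communities: a crossed design of management types x locations x sampling
dates, negative-binomial specimen counts per trap, a reference database of
~507 bp 28S-like marker sequences, and merged amplicon reads whose per-taxon
share follows the forward proportion model

    p_i = n_i * c_i / sum_j n_j * c_j,

where ``n_i`` is the number of specimens of taxon ``i`` in the pool and
``c_i`` its copy-number correction factor (rRNA copies per haploid genome x
genomes per cell x cells per leg).  Every stochastic operation takes an
explicit seed and is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import InfeasibleConfigurationError

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Spike-in calibrator: two fresh beetle legs added to every community pool.
CALIBRATOR_TAXON = "Tenebrio_molitor"
CALIBRATOR_COUNT = 2

#: Per-genus correction factors used by the calibration experiment.  Five
#: are the values the study design is built around (Hylaeus through Bombus);
#: the remainder are fixed plausible values spread log-uniformly over the
#: same 1x-1,248x range.  The calibrator factor is large because fresh
#: tissue yields far more amplifiable DNA than stored specimens.
CALIBRATION_FACTORS: dict[str, float] = {
    "Hylaeus": 1.0,
    "Ceratina": 3.5,
    "Nomada": 7.0,
    "Hoplitis": 14.9,
    "Agapostemon": 18.0,
    "Halictus": 24.0,
    "Lasioglossum": 30.0,
    "Andrena": 42.0,
    "Osmia": 55.0,
    "Eucera": 95.0,
    "Megachile": 124.5,
    "Melissodes": 150.0,
    "Anthophora": 210.0,
    "Svastra": 320.0,
    "Bombus": 1248.0,
}
CALIBRATOR_FACTOR = 450.0

#: Mean per-trap catch for the calibration genera; the four most frequently
#: trapped genera (Agapostemon, Bombus, Hylaeus, Lasioglossum) get the
#: largest means.
CALIBRATION_MEANS: dict[str, float] = {
    "Agapostemon": 6.0,
    "Bombus": 5.0,
    "Hylaeus": 4.0,
    "Lasioglossum": 8.0,
    "Hoplitis": 1.5,
    "Megachile": 1.0,
    "Ceratina": 2.0,
    "Nomada": 1.0,
    "Halictus": 2.5,
    "Andrena": 2.0,
    "Osmia": 1.0,
    "Eucera": 0.8,
    "Melissodes": 1.5,
    "Anthophora": 0.6,
    "Svastra": 0.5,
}


@dataclass(frozen=True)
class StudyDesign:
    """Crossed sampling design: managements x locations x dates.

    One community pool is emitted per (management, location, date) cell,
    with all traps at the site pooled.  The defaults reproduce the survey
    the generator emulates: 2 management types x 4 locations x 28 dates =
    224 community pools, 20 traps per site.
    """

    management_types: tuple[str, ...] = ("CRP", "NPAM")
    locations: tuple[str, ...] = ("Arrowwood", "Kulm", "SullysHill", "Tewaukon")
    sampling_dates: int = 28
    traps_per_site: int = 20

    def __post_init__(self) -> None:
        if not self.management_types or not self.locations:
            raise ValueError("management_types and locations must be non-empty")
        if self.sampling_dates < 1 or self.traps_per_site < 1:
            raise ValueError("sampling_dates and traps_per_site must be >= 1")

    @property
    def n_community_pools(self) -> int:
        return len(self.management_types) * len(self.locations) * self.sampling_dates

    def sample_ids(self) -> list[str]:
        return [
            f"{m}|{loc}|d{d:02d}"
            for m in self.management_types
            for loc in self.locations
            for d in range(1, self.sampling_dates + 1)
        ]


def parse_sample_id(sample_id: str) -> tuple[str, str, str]:
    """Split a ``management|location|date`` community-pool label."""
    management, location, date = sample_id.split("|")
    return management, location, date


@dataclass
class TaxonProfile:
    """Ecological and molecular parameters of one taxon.

    ``true_factor`` is the copy-number correction factor c_i (dimensionless
    fold units); ``mean_abundance`` and ``dispersion`` parameterize the
    per-trap negative binomial with mean m and variance m + m^2/k;
    ``location_effects`` multiplies the mean per location.
    """

    taxon_id: str
    true_factor: float
    mean_abundance: float
    dispersion: float = 0.5
    location_effects: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.true_factor <= 0:
            raise ValueError(f"true_factor must be > 0 for {self.taxon_id}")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0 for {self.taxon_id}")
        if self.mean_abundance < 0:
            raise ValueError(f"mean_abundance must be >= 0 for {self.taxon_id}")

    def mean_at(self, location: str) -> float:
        if self.location_effects is None:
            return self.mean_abundance
        return self.mean_abundance * self.location_effects.get(location, 1.0)


@dataclass
class ReferenceDB:
    """Taxon-labelled marker sequences (one per taxon and locus)."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for taxon, locus, seq in self.records:
            if (taxon, locus) in seen:
                raise ValueError(f"duplicate record for ({taxon}, {locus})")
            seen.add((taxon, locus))
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"sequence for {taxon} is not a non-empty ACGT string")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(self.records)

    @property
    def taxa(self) -> list[str]:
        return [taxon for taxon, _, _ in self.records]

    def sequence(self, taxon_id: str) -> str:
        for taxon, _, seq in self.records:
            if taxon == taxon_id:
                return seq
        raise KeyError(taxon_id)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=f"{taxon}|{locus}", description="")
            for taxon, locus, seq in self.records
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceDB":
        records = []
        for rec in SeqIO.parse(path, "fasta"):
            taxon, _, locus = rec.id.partition("|")
            records.append((taxon, locus or "unknown", str(rec.seq).upper()))
        return cls(records)


@dataclass
class ReadBatch:
    """Merged, chimera-free amplicon reads for one sample.

    ``reads`` holds ``(read_id, sequence, quality)`` triples (Phred+33).
    ``true_counts`` records the simulator's ground-truth per-taxon read
    tally, which downstream tests use as an assignment oracle.
    """

    sample_id: str
    reads: list[tuple[str, str, str]] = field(default_factory=list)
    true_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def to_fastq(self, path) -> None:
        records = []
        for read_id, seq, qual in self.reads:
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            records.append(rec)
        SeqIO.write(records, path, "fastq")

    @classmethod
    def from_fastq(cls, path, sample_id: str) -> "ReadBatch":
        reads = []
        for rec in SeqIO.parse(path, "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            reads.append(
                (rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals))
            )
        return cls(sample_id=sample_id, reads=reads)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, n_subs: int) -> np.ndarray:
    out = seq.copy()
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for pos in positions:
        choices = BASES[BASES != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def generate_reference_db(
    num_taxa: int,
    length: int = 507,
    min_divergence: int = 9,
    seed: int = 0,
    *,
    taxon_ids: Sequence[str] | None = None,
    locus_label: str = "28S",
    max_nearest_divergence: int | None = None,
    max_attempts: int = 1000,
) -> ReferenceDB:
    """Generate one marker sequence per taxon with a divergence floor.

    Every pair of sequences differs at >= ``min_divergence`` positions
    (substitutions only; all sequences share the same length).  The default
    floor of 9 on a 507 bp locus mimics a well-discriminating marker whose
    median nearest-neighbour distance is 9 nt.

    When ``max_nearest_divergence`` is given, each new sequence is derived
    from a previously accepted one by a small number of substitutions
    (between ``max(min_divergence, 1)`` and ``max_nearest_divergence``),
    producing a poorly discriminating low-divergence locus whose taxa
    collapse under identity-threshold mapping.

    Raises
    ------
    InfeasibleConfigurationError
        If rejection sampling fails ``max_attempts`` times for a sequence.
    """
    if num_taxa < 1:
        raise ValueError("num_taxa must be >= 1")
    if min_divergence >= length:
        raise ValueError("min_divergence must be < length")
    if max_nearest_divergence is not None and max_nearest_divergence < max(
        min_divergence, 1
    ):
        raise ValueError("max_nearest_divergence must be >= max(min_divergence, 1)")
    if taxon_ids is None:
        width = len(str(num_taxa))
        taxon_ids = [f"taxon{i + 1:0{width}d}" for i in range(num_taxa)]
    elif len(taxon_ids) != num_taxa:
        raise ValueError("taxon_ids length must equal num_taxa")

    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = [_random_sequence(rng, length)]
    while len(accepted) < num_taxa:
        ok = False
        for _ in range(max_attempts):
            if max_nearest_divergence is None:
                candidate = _random_sequence(rng, length)
            else:
                parent = accepted[rng.integers(len(accepted))]
                n_subs = int(
                    rng.integers(max(min_divergence, 1), max_nearest_divergence + 1)
                )
                candidate = _mutate(rng, parent, n_subs)
            if all(
                int((candidate != prev).sum()) >= min_divergence for prev in accepted
            ):
                accepted.append(candidate)
                ok = True
                break
        if not ok:
            raise InfeasibleConfigurationError(
                f"could not place sequence {len(accepted) + 1}/{num_taxa} after "
                f"{max_attempts} attempts (length={length}, "
                f"min_divergence={min_divergence})"
            )
    return ReferenceDB(
        [
            (taxon, locus_label, seq.tobytes().decode("ascii"))
            for taxon, seq in zip(taxon_ids, accepted)
        ]
    )


def generate_specimen_table(
    design: StudyDesign, profiles: Sequence[TaxonProfile], seed: int = 0
) -> pd.DataFrame:
    """Draw a community pool per design cell: traps summed, NB per trap.

    Returns a samples x taxa DataFrame of specimen counts; one row per
    (management, location, date) cell, entries summed over
    ``design.traps_per_site`` independent negative-binomial trap catches
    with mean ``profile.mean_at(location)`` and size ``profile.dispersion``.
    """
    if not profiles:
        raise ValueError("at least one TaxonProfile is required")
    rng = np.random.default_rng(seed)
    sample_ids = design.sample_ids()
    counts = np.zeros((len(sample_ids), len(profiles)), dtype=np.int64)
    for j, prof in enumerate(profiles):
        for i, sid in enumerate(sample_ids):
            _, location, _ = parse_sample_id(sid)
            m = prof.mean_at(location)
            if m == 0:
                continue
            k = prof.dispersion
            # numpy's NB(n, p) has mean n(1-p)/p; n=k, p=k/(k+m) gives mean m.
            draws = rng.negative_binomial(k, k / (k + m), design.traps_per_site)
            counts[i, j] = draws.sum()
    return pd.DataFrame(
        counts, index=pd.Index(sample_ids, name="sample_id"),
        columns=[p.taxon_id for p in profiles],
    )


def taxa_pool_table(table: pd.DataFrame) -> pd.DataFrame:
    """Build the per-taxon leg pools from a community specimen table.

    One pool per taxon observed anywhere in the survey, holding one leg per
    specimen of that taxon (all samples pooled); the complementary leg of
    every specimen went into its community pool.  Rows are labelled
    ``pool|<taxon>`` and the matrix is diagonal.
    """
    totals = table.sum(axis=0)
    present = totals[totals > 0]
    pools = pd.DataFrame(
        np.diag(present.to_numpy()),
        index=pd.Index([f"pool|{t}" for t in present.index], name="sample_id"),
        columns=present.index,
    )
    return pools


def _phred_char(per_base_error: float) -> str:
    if per_base_error <= 0:
        q = 40
    else:
        q = int(round(-10.0 * math.log10(per_base_error)))
        q = min(40, max(2, q))
    return chr(q + 33)


def _apply_errors(
    rng: np.random.Generator, template: np.ndarray, n_reads: int, error: float
) -> list[str]:
    """Copy a reference ``n_reads`` times with i.i.d. substitution errors."""
    length = len(template)
    out: list[str] = []
    chunk = max(1, min(n_reads, 2_000_000 // max(length, 1)))
    code = np.searchsorted(BASES, template)  # BASES is sorted (A<C<G<T)
    done = 0
    while done < n_reads:
        m = min(chunk, n_reads - done)
        errs = rng.random((m, length)) < error
        shift = rng.integers(1, 4, (m, length))
        codes = (code[None, :] + shift * errs) % 4
        block = BASES[codes]
        out.extend(row.tobytes().decode("ascii") for row in block)
        done += m
    return out


def simulate_reads(
    table: pd.DataFrame,
    profiles: Sequence[TaxonProfile],
    refdb: ReferenceDB,
    reads_per_sample: int = 20_000,
    per_base_error: float = 0.001,
    dropout_prob: float = 0.0,
    calibrator_count: int = CALIBRATOR_COUNT,
    seed: int = 0,
    *,
    calibrator_taxon: str = CALIBRATOR_TAXON,
) -> list[ReadBatch]:
    """Simulate merged amplicon reads for every sample in ``table``.

    Each specimen independently survives tissue degradation with probability
    ``1 - dropout_prob`` (the calibrator legs are fresh and never drop out).
    Reads are a multinomial draw of size ``reads_per_sample`` with per-taxon
    probability proportional to ``(surviving n_i + calibrator spike) * c_i``,
    then copied from the taxon's reference with i.i.d. substitution errors at
    ``per_base_error`` and a constant quality string consistent with that
    rate.  A sample whose surviving mass is zero yields an all-calibrator
    (or, without a spike, empty) batch — the simulated analogue of a failed
    sample.
    """
    factors = {p.taxon_id: p.true_factor for p in profiles}
    missing = [t for t in table.columns if t not in factors]
    if missing:
        raise ValueError(f"profiles missing for taxa: {missing}")
    taxa = list(table.columns)
    if calibrator_count > 0 and calibrator_taxon not in factors:
        raise ValueError(f"no profile for calibrator taxon {calibrator_taxon!r}")
    emit_taxa = taxa + (
        [calibrator_taxon] if calibrator_count > 0 and calibrator_taxon not in taxa
        else []
    )
    templates = {
        t: np.frombuffer(refdb.sequence(t).encode("ascii"), dtype=np.uint8)
        for t in emit_taxa
    }
    qual_char = _phred_char(per_base_error)

    rng = np.random.default_rng(seed)
    batches: list[ReadBatch] = []
    for sample_id, row in table.iterrows():
        n = row.to_numpy(dtype=np.int64)
        surviving = (
            rng.binomial(n, 1.0 - dropout_prob) if dropout_prob > 0 else n.copy()
        )
        eff = {t: float(surviving[j]) for j, t in enumerate(taxa)}
        eff[calibrator_taxon] = eff.get(calibrator_taxon, 0.0) + calibrator_count
        mass = np.array([eff.get(t, 0.0) * factors[t] for t in emit_taxa])
        total = mass.sum()
        batch = ReadBatch(sample_id=str(sample_id))
        if total > 0:
            draws = rng.multinomial(reads_per_sample, mass / total)
            serial = 0
            for t, n_reads in zip(emit_taxa, draws):
                if n_reads == 0:
                    continue
                batch.true_counts[t] = int(n_reads)
                if per_base_error > 0:
                    seqs = _apply_errors(rng, templates[t], int(n_reads), per_base_error)
                else:
                    ref = templates[t].tobytes().decode("ascii")
                    seqs = [ref] * int(n_reads)
                qual = qual_char * len(templates[t])
                for s in seqs:
                    batch.reads.append((f"{sample_id}/read{serial}", s, qual))
                    serial += 1
        batches.append(batch)
    return batches


def default_profiles(
    num_taxa: int = 56,
    seed: int = 7,
    *,
    include_calibrator: bool = True,
    location_structure: bool = True,
    locations: Sequence[str] = StudyDesign().locations,
) -> list[TaxonProfile]:
    """Default 56-taxon survey community plus the beetle calibrator.

    The 15 calibration genera carry their fixed factors and means; the
    remaining taxa get log-spread correction factors over the 1x-1,248x
    range and rarer mean abundances.  When ``location_structure`` is set,
    each non-calibration taxon is boosted at one "home" location, giving
    communities that differ more between locations than between management
    types — the spatial pattern the ordination analytics are meant to
    detect.
    """
    rng = np.random.default_rng(seed)
    profiles: list[TaxonProfile] = []
    for genus, factor in CALIBRATION_FACTORS.items():
        profiles.append(
            TaxonProfile(
                taxon_id=genus,
                true_factor=factor,
                mean_abundance=CALIBRATION_MEANS[genus],
                dispersion=0.5,
            )
        )
    n_extra = max(0, num_taxa - len(profiles))
    extra_factors = np.exp(rng.uniform(np.log(1.0), np.log(1248.0), n_extra))
    extra_means = np.exp(rng.uniform(np.log(0.05), np.log(1.5), n_extra))
    for i in range(n_extra):
        effects = None
        if location_structure:
            home = locations[i % len(locations)]
            effects = {loc: (4.0 if loc == home else 0.25) for loc in locations}
        profiles.append(
            TaxonProfile(
                taxon_id=f"Taxon{len(profiles) + 1:02d}",
                true_factor=float(extra_factors[i]),
                mean_abundance=float(extra_means[i]),
                dispersion=0.5,
                location_effects=effects,
            )
        )
    profiles = profiles[:num_taxa]
    if include_calibrator:
        profiles.append(
            TaxonProfile(
                taxon_id=CALIBRATOR_TAXON,
                true_factor=CALIBRATOR_FACTOR,
                mean_abundance=0.0,
            )
        )
    return profiles


def simulate_calibration_tables(
    profiles: Sequence[TaxonProfile] | None = None,
    n_samples: int = 15,
    seed: int = 0,
    *,
    mean: float = 3.0,
    dispersion: float = 0.8,
    calibrator_count: int = CALIBRATOR_COUNT,
    calibrator_taxon: str = CALIBRATOR_TAXON,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noiseless calibration pair: specimen counts and exact read shares.

    Draws ``n_samples`` specimen pools over the calibration genera
    (negative binomial per sample, every genus forced present in at least
    one sample so its factor is identifiable) and sets the "observed" read
    table exactly to the forward-model proportions computed from the true
    factors, with the calibrator spike included.  By construction every
    sample is perfectly concordant between the two tables.

    Returns ``(specimens, reads)``: specimens excludes the calibrator
    (the model re-adds the spike), reads includes a calibrator column.
    """
    if profiles is None:
        profiles = [
            TaxonProfile(t, f, CALIBRATION_MEANS.get(t, 1.0), dispersion)
            for t, f in CALIBRATION_FACTORS.items()
        ] + [TaxonProfile(calibrator_taxon, CALIBRATOR_FACTOR, 0.0)]
    bee = [p for p in profiles if p.taxon_id != calibrator_taxon]
    cal = [p for p in profiles if p.taxon_id == calibrator_taxon]
    if not cal:
        raise ValueError(f"profiles must include calibrator {calibrator_taxon!r}")
    rng = np.random.default_rng(seed)
    k = dispersion
    counts = rng.negative_binomial(k, k / (k + mean), size=(n_samples, len(bee)))
    for j in range(len(bee)):
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_samples), j] = 1
    samples = [f"cal{s + 1:02d}" for s in range(n_samples)]
    specimens = pd.DataFrame(
        counts, index=pd.Index(samples, name="sample_id"),
        columns=[p.taxon_id for p in bee],
    )
    factors = np.array([p.true_factor for p in bee] + [cal[0].true_factor])
    full = np.hstack([counts, np.full((n_samples, 1), calibrator_count)])
    mass = full * factors
    props = mass / mass.sum(axis=1, keepdims=True)
    reads = pd.DataFrame(
        props, index=specimens.index,
        columns=[p.taxon_id for p in bee] + [calibrator_taxon],
    )
    return specimens, reads
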