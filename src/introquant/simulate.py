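"""Synthetic reference panels and read sets for introgression analyses.

This module generates the inputs the rest of the pipeline consumes: per-genus
reference panels (one representative individual's nuclear loci per species),
admixed single-end read sets per louse individual, and index-swap
contamination between samples.  The generative model is deliberately simple —
a star phylogeny per genus with Jukes-Cantor-like substitutions and no indels
— because the downstream coverage-ratio statistic only responds to which
species a read matches best, not to within-genus topology.

All randomness flows through explicit integer seeds so that identical
configurations produce byte-identical FASTA/FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelSpec",
    "IndividualSpec",
    "SwapSpec",
    "StudyConfig",
    "ReferencePanel",
    "ReadSet",
    "StudyBundle",
    "generate_panel",
    "simulate_reads",
    "inject_index_swap",
    "generate_study",
    "paper71_config",
]

# base encoding used throughout: A=0, C=1, G=2, T=3
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0-3."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class PanelSpec:
    """Parameters for one genus' reference panel.

    ``interspecific_divergence`` is the expected pairwise substitution
    fraction between any two species of the genus (each species' copy of a
    locus mutates independently at rate divergence/2 from a shared ancestral
    sequence, so pairwise divergence is ~= the nominal value minus a small
    multiple-hit correction d^2/3).
    """

    genus_name: str
    n_species: int
    n_loci: int
    locus_length_mean: float
    locus_length_sd: float
    interspecific_divergence: float
    gc_content: float = 0.38
    seed: int = 0
    # hard floor on generated locus lengths; simulate_reads additionally
    # requires every locus to be at least one read long
    locus_length_min: int = 150

    def __post_init__(self) -> None:
        _require(self.n_species >= 2, "n_species", "need at least 2 species")
        _require(self.n_loci >= 1, "n_loci", "need at least 1 locus")
        _require(
            0.0 < self.interspecific_divergence < 0.75,
            "interspecific_divergence",
            "must be in (0, 0.75)",
        )
        _require(0.0 < self.gc_content < 1.0, "gc_content", "must be in (0, 1)")
        _require(self.locus_length_mean > 0, "locus_length_mean", "must be > 0")
        _require(self.locus_length_sd >= 0, "locus_length_sd", "must be >= 0")

    @property
    def species_names(self) -> list[str]:
        return [f"{self.genus_name}_sp{i + 1}" for i in range(self.n_species)]


@dataclass(frozen=True)
class IndividualSpec:
    """One sequenced louse individual: focal species plus read-level admixture.

    ``admixture`` maps donor species to the fraction of reads drawn from that
    donor's genome copy; the remainder come from the focal species.  ``depth``
    is mean fold-coverage over the panel's loci.
    """

    sample_id: str
    genus: str
    focal_species: str
    admixture: Mapping[str, float] = field(default_factory=dict)
    depth: float = 30.0
    read_length: int = 150
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.admixture.values()))
        _require(all(a >= 0 for a in self.admixture.values()), "admixture", "fractions must be >= 0")
        _require(total < 1.0, "admixture", f"donor fractions sum to {total}; must be < 1")
        _require(self.depth > 0, "depth", "must be > 0")
        _require(0.0 <= self.error_rate < 0.1, "error_rate", "must be in [0, 0.1)")
        _require(self.read_length >= 1, "read_length", "must be >= 1")
        _require(self.focal_species not in self.admixture, "admixture", "focal species cannot be its own donor")


@dataclass(frozen=True)
class SwapSpec:
    """Index-swapping contamination: each read independently moves to a
    uniformly chosen other sample with probability ``swap_rate`` (the 1-9%
    range reported for multiplexed Illumina runs)."""

    swap_rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        _require(0.0 <= self.swap_rate <= 0.09, "swap_rate", "must be in [0, 0.09]")


class ReferencePanel:
    """Per-genus reference: species -> locus -> sequence (uint8 codes).

    All species share the same locus ids and lengths (the generator applies
    substitutions only, no indels).  Sequences are stored encoded; use
    :meth:`sequence` for strings.
    """

    def __init__(
        self,
        genus: str,
        species: Sequence[str],
        locus_ids: Sequence[str],
        lengths: Sequence[int],
        seqs: Mapping[tuple[str, str], np.ndarray],
    ) -> None:
        self.genus = genus
        self.species = list(species)
        self.locus_ids = list(locus_ids)
        self.lengths = {loc: int(n) for loc, n in zip(locus_ids, lengths)}
        self.seqs = dict(seqs)

    @property
    def total_length(self) -> int:
        """Reference length of one species (all species are equal here)."""
        return sum(self.lengths.values())

    def sequence(self, species: str, locus: str) -> str:
        return decode_seq(self.seqs[(species, locus)])

    def species_concat(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated codes for one species plus per-locus start offsets."""
        parts = [self.seqs[(species, loc)] for loc in self.locus_ids]
        starts = np.concatenate([[0], np.cumsum([p.size for p in parts])[:-1]])
        return np.concatenate(parts), starts.astype(np.int64)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ReferencePanel({self.genus!r}, {len(self.species)} species, "
            f"{len(self.locus_ids)} loci, {self.total_length} bp/species)"
        )


@dataclass
class ReadSet:
    """Reads of one sample, with hidden true origins for oracle tests.

    ``orig_sample`` records the sample each read was simulated for; after
    index swapping it can differ from ``sample_id``.
    """

    sample_id: str
    genus: str
    focal_species: str
    read_length: int
    seqs: np.ndarray  # (n, read_length) uint8 codes
    true_species: np.ndarray  # (n,) unicode
    locus: np.ndarray  # (n,) unicode
    pos: np.ndarray  # (n,) int64, 0-based start within locus
    orig_sample: np.ndarray  # (n,) unicode

    @property
    def n_reads(self) -> int:
        return int(self.seqs.shape[0])

    def read_names(self) -> list[str]:
        """Names of the form sample:true_species:locus:pos (origin-tagged)."""
        return [
            f"{s}:{sp}:{loc}:{p}"
            for s, sp, loc, p in zip(self.orig_sample, self.true_species, self.locus, self.pos)
        ]

    def read_strings(self) -> list[str]:
        return [decode_seq(row) for row in self.seqs]


@dataclass
class StudyBundle:
    panels: dict[str, ReferencePanel]
    readsets: list[ReadSet]
    truth: pd.DataFrame


def generate_panel(spec: PanelSpec) -> ReferencePanel:
    """Generate one genus' panel from a star phylogeny.

    Each locus has an ancestral sequence with the requested GC content; each
    species' copy substitutes every site independently with probability
    divergence/2 to a uniformly chosen different base.
    """
    rng = np.random.default_rng(spec.seed)
    n_loci = spec.n_loci
    lengths = np.maximum(
        np.round(rng.normal(spec.locus_length_mean, spec.locus_length_sd, n_loci)).astype(int),
        spec.locus_length_min,
    )
    width = max(4, len(str(n_loci)))
    locus_ids = [f"L{i + 1:0{width}d}" for i in range(n_loci)]
    gc = spec.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    half_d = spec.interspecific_divergence / 2.0

    species = spec.species_names
    seqs: dict[tuple[str, str], np.ndarray] = {}
    for loc, length in zip(locus_ids, lengths):
        anc = rng.choice(4, size=length, p=base_p).astype(np.uint8)
        for sp in species:
            mask = rng.random(length) < half_d
            shift = rng.integers(1, 4, size=length, dtype=np.uint8)
            derived = anc.copy()
            derived[mask] = (anc[mask] + shift[mask]) % 4
            seqs[(sp, loc)] = derived
    return ReferencePanel(spec.genus_name, species, locus_ids, lengths, seqs)


def simulate_reads(panel: ReferencePanel, spec: IndividualSpec) -> ReadSet:
    """Simulate single-end reads for one individual.

    Reads start at a uniformly random position of a uniformly random locus;
    each read's source genome is a donor d with probability admixture[d],
    otherwise the focal species.  Per-base substitution errors are i.i.d.
    The expected read count is depth x total locus length / read length.
    """
    for donor in spec.admixture:
        if donor not in panel.species:
            raise ValueError(f"donor species {donor!r} not in panel {panel.genus!r}")
    if spec.focal_species not in panel.species:
        raise ValueError(f"focal species {spec.focal_species!r} not in panel {panel.genus!r}")
    L = spec.read_length
    too_short = [loc for loc, n in panel.lengths.items() if n < L]
    if too_short:
        raise ValueError(f"{len(too_short)} loci shorter than read length {L} (e.g. {too_short[0]})")

    rng = np.random.default_rng(spec.seed)
    total_len = panel.total_length
    n_reads = int(round(spec.depth * total_len / L))

    donors = sorted(spec.admixture)
    sources = donors + [spec.focal_species]
    probs = np.array([spec.admixture[d] for d in donors] + [1.0 - sum(spec.admixture.values())])
    src_idx = rng.choice(len(sources), size=n_reads, p=probs)

    locus_ids = np.asarray(panel.locus_ids)
    lengths = np.array([panel.lengths[loc] for loc in panel.locus_ids], dtype=np.int64)
    loc_idx = rng.integers(0, len(locus_ids), size=n_reads)
    max_start = lengths[loc_idx] - L
    pos = (rng.random(n_reads) * (max_start + 1)).astype(np.int64)

    seqs = np.empty((n_reads, L), dtype=np.uint8)
    offsets = np.arange(L, dtype=np.int64)
    for si, sp in enumerate(sources):
        rows = np.flatnonzero(src_idx == si)
        if rows.size == 0:
            continue
        concat, starts = panel.species_concat(sp)
        gpos = starts[loc_idx[rows]] + pos[rows]
        seqs[rows] = concat[gpos[:, None] + offsets]

    if spec.error_rate > 0:
        # i.i.d. per-base errors, sampled sparsely: draw the total error
        # count, then error sites uniformly over the read matrix
        n_bases = n_reads * L
        n_err = rng.binomial(n_bases, spec.error_rate)
        sites = np.unique(rng.integers(0, n_bases, size=n_err))
        shift = rng.integers(1, 4, size=sites.size, dtype=np.uint8)
        flat = seqs.reshape(-1)
        flat[sites] = (flat[sites] + shift) % 4

    true_species = np.asarray(sources, dtype="U64")[src_idx]
    return ReadSet(
        sample_id=spec.sample_id,
        genus=spec.genus,
        focal_species=spec.focal_species,
        read_length=L,
        seqs=seqs,
        true_species=true_species,
        locus=locus_ids[loc_idx],
        pos=pos,
        orig_sample=np.full(n_reads, spec.sample_id, dtype="U64"),
    )


def inject_index_swap(readsets: Sequence[ReadSet], spec: SwapSpec) -> list[ReadSet]:
    """Reassign reads between samples to emulate index swapping.

    Each read independently moves to a uniformly chosen *other* sample with
    probability ``swap_rate``.  Total read count is conserved; moved reads
    keep their origin tags (``orig_sample``) so the swap is auditable.
    """
    if len(readsets) < 2:
        raise ValueError("index swapping needs at least 2 readsets")
    if len({rs.read_length for rs in readsets}) != 1:
        raise ValueError("index swapping requires equal read lengths across samples")
    rng = np.random.default_rng(spec.seed)
    n_samples = len(readsets)
    kept: list[np.ndarray] = []
    # incoming[dest] -> list of (source sample index, source row indices)
    incoming: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(n_samples)]
    for i, rs in enumerate(readsets):
        move = rng.random(rs.n_reads) < spec.swap_rate
        dest = rng.integers(0, n_samples - 1, size=rs.n_reads)
        dest = np.where(dest >= i, dest + 1, dest)  # uniform over other samples
        kept.append(np.flatnonzero(~move))
        moved_rows = np.flatnonzero(move)
        for d in np.unique(dest[moved_rows]):
            incoming[int(d)].append((i, moved_rows[dest[moved_rows] == d]))

    out: list[ReadSet] = []
    for i, rs in enumerate(readsets):
        # kept reads first (original order), then received reads ordered by
        # source sample then source row — deterministic under the seed
        blocks = [(i, kept[i])] + sorted(incoming[i])
        out.append(
            ReadSet(
                sample_id=rs.sample_id,
                genus=rs.genus,
                focal_species=rs.focal_species,
                read_length=rs.read_length,
                seqs=np.concatenate([readsets[s].seqs[rows] for s, rows in blocks]),
                true_species=np.concatenate([readsets[s].true_species[rows] for s, rows in blocks]),
                locus=np.concatenate([readsets[s].locus[rows] for s, rows in blocks]),
                pos=np.concatenate([readsets[s].pos[rows] for s, rows in blocks]),
                orig_sample=np.concatenate([readsets[s].orig_sample[rows] for s, rows in blocks]),
            )
        )
    return out


@dataclass(frozen=True)
class StudyConfig:
    """Full study layout: panels per genus, one spec per individual, optional
    index swapping applied across all samples."""

    panels: tuple[PanelSpec, ...]
    individuals: tuple[IndividualSpec, ...]
    swap: SwapSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.panels or not self.individuals:
            raise ValueError("config must list at least one genus and one individual")
        ids = [i.sample_id for i in self.individuals]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
        genera = {p.genus_name for p in self.panels}
        for ind in self.individuals:
            if ind.genus not in genera:
                raise ValueError(f"sample {ind.sample_id}: unknown genus {ind.genus!r}")


def generate_study(config: StudyConfig) -> StudyBundle:
    """Generate panels, readsets and the truth table for a whole study.

    Per-individual seeds are derived deterministically from the root seed
    unless an individual carries a nonzero seed of its own.
    """
    panels = {p.genus_name: generate_panel(p) for p in config.panels}
    seed_rng = np.random.default_rng(config.seed)
    derived = seed_rng.integers(0, 2**31 - 1, size=len(config.individuals) + 1)

    readsets = []
    for i, ind in enumerate(config.individuals):
        spec = ind if ind.seed != 0 else replace(ind, seed=int(derived[i]))
        readsets.append(simulate_reads(panels[ind.genus], spec))
    if config.swap is not None and config.swap.swap_rate > 0:
        swap = config.swap if config.swap.seed != 0 else replace(config.swap, seed=int(derived[-1]))
        readsets = inject_index_swap(readsets, swap)

    all_species = sorted({sp for p in panels.values() for sp in p.species})
    rows = []
    for ind in config.individuals:
        row = {
            "sample_id": ind.sample_id,
            "genus": ind.genus,
            "focal_species": ind.focal_species,
        }
        for sp in all_species:
            row[f"alpha_{sp}"] = float(ind.admixture.get(sp, 0.0))
        rows.append(row)
    truth = pd.DataFrame(rows)
    return StudyBundle(panels=panels, readsets=readsets, truth=truth)


def paper71_config(
    seed: int = 0,
    n_loci: tuple[int, int] = (1039, 1095),
    locus_length_mean: float = 350.0,
    locus_length_sd: float = 60.0,
    depth: float = 30.0,
    read_length: int = 150,
    error_rate: float = 0.002,
    swap_rate: float = 0.02,
    wing_alpha: tuple[float, float] = (0.05, 0.25),
    body_alpha: tuple[float, float] = (0.0, 0.08),
) -> StudyConfig:
    """The default two-genus study layout: 71 individuals in a 5-species
    wing-louse genus and a 7-species body-louse genus.

    Wing lice (*Columbicola*) get higher read-level admixture (default
    Uniform(0.05, 0.25) from one random congeneric donor) than body lice
    (Uniform(0, 0.08)), emulating the dispersal-driven introgression contrast;
    the wing genus also gets lower interspecific divergence.  ``n_loci`` is
    (wing, body); pass smaller values for quick runs.
    """
    rng = np.random.default_rng(seed)
    wing = PanelSpec(
        genus_name="Columbicola",
        n_species=5,
        n_loci=n_loci[0],
        locus_length_mean=locus_length_mean,
        locus_length_sd=locus_length_sd,
        interspecific_divergence=0.05,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    body = PanelSpec(
        genus_name="Physconelloides",
        n_species=7,
        n_loci=n_loci[1],
        locus_length_mean=locus_length_mean,
        locus_length_sd=locus_length_sd,
        interspecific_divergence=0.10,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    # 30 wing + 41 body = 71 individuals, spread round-robin over species
    counts = {wing.genus_name: 30, body.genus_name: 41}
    alpha_range = {wing.genus_name: wing_alpha, body.genus_name: body_alpha}
    individuals = []
    for panel in (wing, body):
        species = panel.species_names
        lo, hi = alpha_range[panel.genus_name]
        for i in range(counts[panel.genus_name]):
            focal = species[i % len(species)]
            others = [s for s in species if s != focal]
            donor = others[int(rng.integers(0, len(others)))]
            alpha = float(rng.uniform(lo, hi))
            admix = {donor: alpha} if alpha > 0 else {}
            individuals.append(
                IndividualSpec(
                    sample_id=f"{panel.genus_name[:4]}_{focal.rsplit('sp', 1)[-1]}_{i + 1:02d}",
                    genus=panel.genus_name,
                    focal_species=focal,
                    admixture=admix,
                    depth=depth,
                    read_length=read_length,
                    error_rate=error_rate,
                )
            )
    swap = SwapSpec(swap_rate=swap_rate) if swap_rate > 0 else None
    return StudyConfig(
        panels=(wing, body),
        individuals=tuple(individuals),
        swap=swap,
        seed=seed,
    )
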