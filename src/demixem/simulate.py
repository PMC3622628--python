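"""Synthetic catalogs, abundance profiles, and pure/mixed read sets.

Reads are sampled exactly as the generative model assumes: a transcript is
drawn with probability proportional to abundance times effective length,
then a start position uniformly over the start range compatible with the
effective length (or from an injected positional-bias window). Ambiguity
is induced by exact sequence blocks shared between designated transcript
pairs; the SAM emitter reports every exact placement of a read that falls
inside such a block, so multi-mapping is exercised without an aligner.
All output is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import ReadAlignmentGroup
from .model import (
    AbundanceProfile,
    EffectiveLengths,
    FragmentModel,
    TranscriptCatalog,
    effective_lengths,
    rho_to_alpha,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PositionalBiasSpec:
    """Restrict read starts to a relative window [lo, hi) of the start range."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValueError("need 0 <= lo < hi <= 1")


@dataclass(frozen=True)
class SimConfig:
    n_transcripts: int = 50
    length_range: tuple[int, int] = (500, 2000)
    read_length: int = 75
    n_reads_pure: int = 10_000
    n_reads_mixed: int = 10_000
    tau_b: float = 0.6
    frag: FragmentModel = field(default_factory=FragmentModel)
    bias_spec: PositionalBiasSpec | None = None
    ambiguity: float = 0.0
    concentration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1 or self.n_reads_pure < 1 or self.n_reads_mixed < 1:
            raise ValueError("all counts must be >= 1")
        if not (0.0 <= self.tau_b <= 1.0):
            raise ValueError("tau_b must lie in [0, 1]")
        if not (0.0 <= self.ambiguity <= 1.0):
            raise ValueError("ambiguity must lie in [0, 1]")
        if self.read_length > self.length_range[0]:
            raise ValueError("read_length must not exceed the minimum transcript length")


@dataclass(frozen=True)
class SharedBlock:
    """An exact duplicated block between two transcripts."""

    t1: int
    start1: int
    t2: int
    start2: int
    length: int


@dataclass
class SimRead:
    read_id: str
    transcript: int
    position: int
    cell: str  # "a" or "b"
    placements: list[tuple[int, int]]  # sorted (transcript, position) incl. origin


@dataclass
class GroundTruth:
    """Ledger of true per-read origins and per-transcript counts."""

    rho: AbundanceProfile
    reads: list[SimRead]
    counts_a: np.ndarray
    counts_b: np.ndarray

    @property
    def counts(self) -> np.ndarray:
        return self.counts_a + self.counts_b


@dataclass
class SimulatedSample:
    catalog: TranscriptCatalog
    truth: GroundTruth
    read_length: int
    sample_tag: str = "pure"

    def to_alignment_groups(self) -> list[ReadAlignmentGroup]:
        out = []
        for r in self.truth.reads:
            t, p = zip(*r.placements)
            out.append(
                ReadAlignmentGroup(
                    read_id=r.read_id,
                    transcripts=np.array(t, dtype=np.int64),
                    starts=np.array(p, dtype=np.int64),
                    reverse=np.zeros(len(t), dtype=bool),
                    sample_tag=self.sample_tag,
                )
            )
        return out

    def to_sam(self, path: str) -> None:
        write_sam(path, self.catalog, self.truth.reads, self.read_length)

    def write_ledger(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\ttranscript\tcell_type\tposition\tn_placements\n")
            for r in self.truth.reads:
                fh.write(
                    f"{r.read_id}\t{self.catalog.ids[r.transcript]}\t{r.cell}\t"
                    f"{r.position}\t{len(r.placements)}\n"
                )


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def generate_catalog(config: SimConfig, rng: np.random.Generator | None = None) -> tuple[TranscriptCatalog, list[SharedBlock]]:
    """Random catalog; a fraction of transcripts share exact homologous blocks."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    seqs = [_random_sequence(rng, int(l)) for l in lengths]

    blocks: list[SharedBlock] = []
    n_pairs = int(config.ambiguity * n) // 2
    for k in range(n_pairs):
        t1, t2 = 2 * k, 2 * k + 1
        block_len = min(2 * config.read_length, int(min(lengths[t1], lengths[t2])))
        b1 = int(rng.integers(0, lengths[t1] - block_len + 1))
        b2 = int(rng.integers(0, lengths[t2] - block_len + 1))
        seqs[t2][b2 : b2 + block_len] = seqs[t1][b1 : b1 + block_len]
        blocks.append(SharedBlock(t1=t1, start1=b1, t2=t2, start2=b2, length=block_len))

    catalog = TranscriptCatalog(
        ids=tuple(f"t{i + 1:04d}" for i in range(n)),
        lengths=np.asarray(lengths, dtype=np.int64),
        sequences=tuple(s.tobytes().decode("ascii") for s in seqs),
    )
    return catalog, blocks


def write_fasta(catalog: TranscriptCatalog, path: str, line_width: int = 70) -> None:
    if catalog.sequences is None:
        raise ValueError("catalog has no sequences")
    with open(path, "w") as fh:
        for name, seq in zip(catalog.ids, catalog.sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def generate_abundances(
    catalog: TranscriptCatalog,
    rng: np.random.Generator | int,
    concentration: float = 1.0,
) -> tuple[AbundanceProfile, AbundanceProfile]:
    """Two independent symmetric-Dirichlet abundance profiles."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    conc = np.full(catalog.size, concentration)
    return AbundanceProfile(rng.dirichlet(conc)), AbundanceProfile(rng.dirichlet(conc))


def _start_ranges(
    catalog: TranscriptCatalog, l_eff: EffectiveLengths, read_length: int
) -> np.ndarray:
    """Number of valid start positions per transcript."""
    fit = catalog.lengths - read_length + 1
    return np.maximum(1, np.minimum(np.round(l_eff.l_eff).astype(np.int64), fit))


def _blocks_by_transcript(blocks: list[SharedBlock]) -> dict[int, list[tuple[int, int, int, int]]]:
    by_t: dict[int, list[tuple[int, int, int, int]]] = {}
    for b in blocks:
        by_t.setdefault(b.t1, []).append((b.start1, b.length, b.t2, b.start2))
        by_t.setdefault(b.t2, []).append((b.start2, b.length, b.t1, b.start1))
    return by_t


def _placements(
    t: int, pos: int, read_length: int, by_t: dict[int, list[tuple[int, int, int, int]]]
) -> list[tuple[int, int]]:
    out = [(t, pos)]
    for bstart, blen, t2, b2start in by_t.get(t, ()):
        if pos >= bstart and pos + read_length <= bstart + blen:
            out.append((t2, b2start + (pos - bstart)))
    out.sort()
    return out


def _sample_reads(
    catalog: TranscriptCatalog,
    blocks: list[SharedBlock],
    transcripts: np.ndarray,
    cells: list[str],
    n_starts: np.ndarray,
    bias_spec: PositionalBiasSpec | None,
    read_length: int,
    rng: np.random.Generator,
    id_prefix: str,
) -> list[SimRead]:
    n = len(transcripts)
    u = rng.random(n)
    span = n_starts[transcripts].astype(np.float64)
    if bias_spec is None:
        pos = np.floor(u * span).astype(np.int64)
    else:
        lo = np.floor(bias_spec.lo * span)
        hi = np.maximum(lo + 1, np.ceil(bias_spec.hi * span))
        pos = (lo + np.floor(u * (hi - lo))).astype(np.int64)
    pos = np.minimum(pos, n_starts[transcripts] - 1)
    by_t = _blocks_by_transcript(blocks)
    width = max(6, len(str(n)))
    return [
        SimRead(
            read_id=f"{id_prefix}{i:0{width}d}",
            transcript=int(t),
            position=int(p),
            cell=cells[i],
            placements=_placements(int(t), int(p), read_length, by_t),
        )
        for i, (t, p) in enumerate(zip(transcripts, pos))
    ]


def _counts(reads: list[SimRead], size: int) -> tuple[np.ndarray, np.ndarray]:
    ca = np.zeros(size)
    cb = np.zeros(size)
    for r in reads:
        (ca if r.cell == "a" else cb)[r.transcript] += 1
    return ca, cb


def generate_reads(
    catalog: TranscriptCatalog,
    blocks: list[SharedBlock],
    rho: AbundanceProfile,
    n_reads: int,
    frag: FragmentModel,
    read_length: int,
    rng: np.random.Generator | int,
    bias_spec: PositionalBiasSpec | None = None,
    id_prefix: str = "p",
    cell: str = "a",
    sample_tag: str = "pure",
) -> SimulatedSample:
    """One homogeneous read set drawn from a single abundance profile."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    l_eff = effective_lengths(catalog, frag)
    alpha = rho_to_alpha(rho, l_eff).alpha
    transcripts = rng.choice(catalog.size, size=n_reads, p=alpha)
    n_starts = _start_ranges(catalog, l_eff, read_length)
    reads = _sample_reads(
        catalog, blocks, transcripts, [cell] * n_reads, n_starts, bias_spec,
        read_length, rng, id_prefix,
    )
    ca, cb = _counts(reads, catalog.size)
    truth = GroundTruth(rho=rho, reads=reads, counts_a=ca, counts_b=cb)
    return SimulatedSample(catalog=catalog, truth=truth, read_length=read_length, sample_tag=sample_tag)


def generate_mixture(
    catalog: TranscriptCatalog,
    blocks: list[SharedBlock],
    rho_a: AbundanceProfile,
    rho_b: AbundanceProfile,
    tau_b: float,
    n_reads: int,
    frag: FragmentModel,
    read_length: int,
    rng: np.random.Generator | int,
    bias_spec: PositionalBiasSpec | None = None,
    id_prefix: str = "m",
) -> SimulatedSample:
    """Mixed read set: each read's cell type is Bernoulli(tau_b), then the
    read is drawn from that cell type's profile."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not (0.0 <= tau_b <= 1.0):
        raise ValueError("tau_b must lie in [0, 1]")
    l_eff = effective_lengths(catalog, frag)
    alpha_a = rho_to_alpha(rho_a, l_eff).alpha
    alpha_b = rho_to_alpha(rho_b, l_eff).alpha

    is_b = rng.random(n_reads) < tau_b
    n_b = int(is_b.sum())
    draws_a = rng.choice(catalog.size, size=n_reads - n_b, p=alpha_a) if n_reads > n_b else np.empty(0, np.int64)
    draws_b = rng.choice(catalog.size, size=n_b, p=alpha_b) if n_b else np.empty(0, np.int64)
    transcripts = np.empty(n_reads, dtype=np.int64)
    transcripts[~is_b] = draws_a
    transcripts[is_b] = draws_b
    cells = ["b" if f else "a" for f in is_b]

    n_starts = _start_ranges(catalog, l_eff, read_length)
    reads = _sample_reads(
        catalog, blocks, transcripts, cells, n_starts, bias_spec, read_length, rng, id_prefix
    )
    ca, cb = _counts(reads, catalog.size)
    rho_m = AbundanceProfile((1.0 - tau_b) * rho_a.rho + tau_b * rho_b.rho)
    truth = GroundTruth(rho=rho_m, reads=reads, counts_a=ca, counts_b=cb)
    return SimulatedSample(catalog=catalog, truth=truth, read_length=read_length, sample_tag="mixed")


def extract_cell_subset(sample: SimulatedSample, cell: str) -> list[SimRead]:
    """Reads of the mixture that truly originate from one cell type."""
    return [r for r in sample.truth.reads if r.cell == cell]


def write_sam(path: str, catalog: TranscriptCatalog, reads: list[SimRead], read_length: int) -> None:
    """Plain-text SAM with one record per exact placement, name-grouped."""
    if catalog.sequences is None:
        raise ValueError("catalog has no sequences")
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, l in zip(catalog.ids, catalog.lengths):
            fh.write(f"@SQ\tSN:{name}\tLN:{int(l)}\n")
        for r in reads:
            seq = catalog.sequences[r.transcript][r.position : r.position + read_length]
            for k, (t, p) in enumerate(r.placements):
                flag = 0 if k == 0 else 256
                fh.write(
                    f"{r.read_id}\t{flag}\t{catalog.ids[t]}\t{p + 1}\t255\t"
                    f"{read_length}M\t*\t0\t0\t{seq}\t*\n"
                )
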