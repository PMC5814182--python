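"""Toy reference genomes with a mouse-like karyotype.

The simulated genomes mirror the murine setting of the analysis: autosomes
named "1".."19" (configurable count), optional "X"/"Y" allosomes at a single
expected copy (male baseline), and optional non-genomic transgene contigs
(e.g. "huYAP", "muAkt") against which transgene integration detection is
exercised. Sequences are random with smoothly varying GC so that a
GC-dependent coverage bias can be planted and then removed by normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_GC_RHO = 0.95  # AR(1) autocorrelation of the per-bin GC target


@dataclass
class GenomeModel:
    """A reference genome description at a fixed analysis bin size.

    ``chromosomes`` is ordered (karyotype order) and includes transgene
    contigs; ``gc`` holds one per-bin GC-fraction array per contig;
    ``sequence`` is optional and, when present, is exactly consistent with
    ``gc``. ``expected_copies`` is the per-contig copy-number baseline
    (2 for autosomes, 1 for X/Y in the male default).
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int
    transgenes: tuple[str, ...] = ()
    gc: dict[str, np.ndarray] = field(default_factory=dict)
    sequence: dict[str, str] | None = None
    expected_copies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        for tg in self.transgenes:
            if tg not in names:
                raise ValueError(f"transgene contig {tg!r} not among chromosomes")
        for name, length in self.chromosomes:
            if name in self.gc and len(self.gc[name]) != self.n_bins(name):
                raise ValueError(
                    f"gc track of {name!r} has {len(self.gc[name])} bins, "
                    f"expected {self.n_bins(name)}"
                )
        if not self.expected_copies:
            self.expected_copies = {
                name: (1 if name in ("X", "Y") else 2)
                for name in names
                if name not in self.transgenes
            }

    # ------------------------------------------------------------------
    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def genomic_chromosomes(self) -> list[str]:
        return [n for n, _ in self.chromosomes if n not in self.transgenes]

    @property
    def autosomes(self) -> list[str]:
        return [n for n in self.genomic_chromosomes if self.expected_copies.get(n, 2) == 2]

    def is_transgene(self, name: str) -> bool:
        return name in self.transgenes

    def n_bins(self, name: str) -> int:
        return math.ceil(self.lengths[name] / self.bin_size)

    @property
    def rank(self) -> dict[str, int]:
        """Deterministic total order of contigs (karyotype order)."""
        return {n: i for i, n in enumerate(self.names)}

    def validate_locus(self, chrom: str, pos: int) -> None:
        if chrom not in self.lengths:
            known = ", ".join(self.names)
            raise ValueError(f"unknown chromosome {chrom!r}; known: {known}")
        if not 0 <= pos < self.lengths[chrom]:
            raise ValueError(f"position {pos} outside chromosome {chrom!r} (length {self.lengths[chrom]})")

    def check_gc_consistency(self, tol: float = 1e-9) -> None:
        """Verify the GC track against the stored sequence, when present."""
        if self.sequence is None:
            return
        for name, _ in self.chromosomes:
            seq = np.frombuffer(self.sequence[name].encode(), dtype="S1")
            is_gc = (seq == b"G") | (seq == b"C")
            nb = self.n_bins(name)
            idx = np.arange(len(seq)) // self.bin_size
            counts = np.bincount(idx, weights=is_gc.astype(float), minlength=nb)
            widths = np.bincount(idx, minlength=nb)
            frac = counts / widths
            if not np.allclose(frac, self.gc[name], atol=tol, rtol=0):
                raise AssertionError(f"gc track of {name!r} inconsistent with sequence")


def _gc_target(n_bins: int, rng: np.random.Generator, gc_mean: float, gc_amplitude: float) -> np.ndarray:
    """Smooth per-bin GC target: clipped AR(1) around ``gc_mean``."""
    eps = rng.standard_normal(n_bins)
    ar = np.empty(n_bins)
    acc = 0.0
    scale = math.sqrt(1.0 - _GC_RHO**2)
    for i in range(n_bins):
        acc = _GC_RHO * acc + scale * eps[i]
        ar[i] = acc
    return np.clip(gc_mean + gc_amplitude * ar, 0.25, 0.65)


def _random_chrom(
    length: int,
    bin_size: int,
    rng: np.random.Generator,
    gc_mean: float,
    gc_amplitude: float,
    with_sequence: bool,
) -> tuple[np.ndarray, str | None]:
    n_bins = math.ceil(length / bin_size)
    target = _gc_target(n_bins, rng, gc_mean, gc_amplitude)
    if not with_sequence:
        return target, None
    per_base = np.repeat(target, bin_size)[:length]
    is_gc = rng.random(length) < per_base
    which = rng.integers(0, 2, size=length)
    bases = np.where(is_gc, np.where(which == 0, b"G", b"C"), np.where(which == 0, b"A", b"T"))
    idx = np.arange(length) // bin_size
    counts = np.bincount(idx, weights=is_gc.astype(float), minlength=n_bins)
    widths = np.bincount(idx, minlength=n_bins)
    return counts / widths, bases.tobytes().decode()


def make_toy_genome(
    n_autosomes: int,
    autosome_length: int = 1_000_000,
    bin_size: int = 1000,
    include_allosomes: bool = False,
    transgenes: tuple[str, ...] | list[str] = (),
    seed: int = 0,
    with_sequence: bool = True,
    gc_mean: float = 0.45,
    gc_amplitude: float = 0.12,
    transgene_length: int = 3000,
) -> GenomeModel:
    """Generate a toy genome with autosomes "1".."n" (+ "X","Y" if asked).

    GC content varies smoothly along each chromosome so that a planted
    GC-coverage bias is identifiable. Deterministic for a fixed seed; with
    ``with_sequence=False`` only the GC track is drawn (large-scale runs
    where no FASTA is needed).
    """
    if n_autosomes < 1:
        raise ValueError(f"n_autosomes must be >= 1, got {n_autosomes}")
    if autosome_length <= 0:
        raise ValueError(f"autosome_length must be positive, got {autosome_length}")
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if autosome_length < 10 * bin_size:
        raise ValueError(
            f"autosome_length ({autosome_length}) must be >= 10 x bin_size ({bin_size})"
        )
    if transgene_length <= 0:
        raise ValueError(f"transgene_length must be positive, got {transgene_length}")

    rng = np.random.default_rng(seed)
    chromosomes: list[tuple[str, int]] = [(str(i + 1), autosome_length) for i in range(n_autosomes)]
    if include_allosomes:
        chromosomes.append(("X", autosome_length))
        chromosomes.append(("Y", max(autosome_length // 2, 10 * bin_size)))
    for tg in transgenes:
        chromosomes.append((tg, transgene_length))

    gc: dict[str, np.ndarray] = {}
    sequence: dict[str, str] | None = {} if with_sequence else None
    for name, length in chromosomes:
        track, seq = _random_chrom(length, bin_size, rng, gc_mean, gc_amplitude, with_sequence)
        gc[name] = track
        if with_sequence:
            assert sequence is not None and seq is not None
            sequence[name] = seq

    return GenomeModel(
        chromosomes=chromosomes,
        bin_size=bin_size,
        transgenes=tuple(transgenes),
        gc=gc,
        sequence=sequence,
    )
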