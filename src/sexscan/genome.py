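"""Genome model: an ordered set of named chromosomes with lengths.

The default genome mirrors a small cyclically parthenogenetic crustacean
karyotype with a haploid chromosome number of 10; chromosome lengths are
equal unless stated otherwise, which is all the windowed coverage
arithmetic needs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass


@dataclass(frozen=True)
class GenomeModel:
    """Ordered collection of (chromosome name, length in bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def default(cls, n_chromosomes: int = 10, length: int = 1_000_000,
                prefix: str = "chr") -> "GenomeModel":
        """Equal-length genome; 10 chromosomes of 1 Mb unless overridden."""
        return cls(tuple((f"{prefix}{i + 1}", length) for i in range(n_chromosomes)))

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "GenomeModel":
        """Read a genome from a 2-column TSV (name, length) or a .fai index.

        A .fai has five tab-separated columns; only the first two are used,
        so the same parser covers both layouts.
        """
        chroms: list[tuple[str, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected at least "
                                     f"2 tab-separated columns, got {len(parts)}")
                try:
                    length = int(parts[1])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: length {parts[1]!r} "
                                     f"is not an integer") from exc
                chroms.append((parts[0], length))
        return cls(tuple(chroms))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        """Validate a 1-based closed interval against the genome bounds."""
        if chrom not in self.lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        length = self.lengths[chrom]
        if not (1 <= start <= end <= length):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds 1-{length}")

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")
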