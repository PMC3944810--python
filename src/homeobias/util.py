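"""Shared small helpers and constants."""
from __future__ import annotations

import hashlib
from pathlib import Path

GENOTYPES = ("WT", "Li2")
SUBGENOMES = ("A", "D")
CATEGORIES = ("A", "D", "X", "N")


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration value."""


class InternalConsistencyError(RuntimeError):
    """A generated artifact violated one of its construction invariants."""


def percent(k: float, n: float, ndigits: int = 1) -> float:
    """Percentage 100*k/n on the 0-100 scale, rounded to `ndigits` decimals.

    This is the rounding convention used by every summary table in the
    package (read-category percentages, expressed-gene percentages, bias
    prevalences).
    """
    if n <= 0:
        raise ValueError(f"denominator must be positive, got {n}")
    return round(100.0 * k / n, ndigits)


def library_name(genotype: str, replicate: int) -> str:
    """Canonical library id, e.g. 'WT_1' for wild-type biological replicate 1."""
    return f"{genotype}_{replicate}"


def library_genotype(library: str) -> str:
    """Recover the genotype factor level from a library id."""
    geno = library.rsplit("_", 1)[0]
    if geno not in GENOTYPES:
        raise ValueError(f"library {library!r} does not encode a known genotype")
    return geno


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
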