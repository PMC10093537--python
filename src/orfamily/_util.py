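"""Small shared helpers: sequences, deterministic seeding, percentage formatting."""

from __future__ import annotations

import hashlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(dna: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return dna.translate(_COMPLEMENT)[::-1]


def stage_seed(seed: int, stage: str) -> int:
    """Derive an independent, stable sub-seed for a named pipeline stage.

    Hashing (seed, stage) means toggling one stage never shifts the random
    stream of another.  Result is kept below 2**31.
    """
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))


def format_percent(num: float, den: float, style: str = "one_decimal_or_int") -> str:
    """Render num/den as a percentage string in one of the report's styles.

    styles:
      two_decimal        -> "36.23"
      one_decimal_or_int -> "87.4" but "95" when the one-decimal value is whole
      int                -> "20"
    """
    if den == 0:
        return "0"
    pct = 100.0 * num / den
    if style == "two_decimal":
        return f"{pct:.2f}"
    if style == "int":
        return f"{round(pct):d}"
    if style == "one_decimal_or_int":
        one = round(pct, 1)
        if float(one).is_integer():
            return f"{int(one):d}"
        return f"{one:.1f}"
    raise ValueError(f"unknown percent style: {style!r}")


def percent_value(num: float, den: float, style: str = "one_decimal_or_int") -> float:
    """Numeric value of format_percent (e.g. 36.23, 87.4, 95.0)."""
    return float(format_percent(num, den, style))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()
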