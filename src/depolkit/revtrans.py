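"""Reverse translation of a protein into DNA via a codon-usage table.

The packaged table (``sf9.cut``) is a plain three-column text file: codon,
one-letter amino acid ('*' marks stops), synonymous-usage fraction.  The
reader renormalizes fractions per amino acid and validates coverage of all
61 sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Seq import Seq

from .errors import DataError
from .seqio import AA_ALPHABET

_DNA = set("ACGT")


@dataclass(frozen=True)
class CodonUsageTable:
    """Per amino acid: codons with normalized usage fractions."""

    codons: dict[str, tuple[tuple[str, float], ...]]  # aa -> ((codon, frac),)
    stops: tuple[tuple[str, float], ...]

    def top_codon(self, aa: str) -> str:
        try:
            options = self.codons[aa]
        except KeyError:
            raise DataError(f"amino acid {aa!r} absent from codon table")
        # deterministic: highest fraction, codon string breaks exact ties
        return max(options, key=lambda cf: (cf[1], cf[0]))[0]


def parse_codon_table(text: str) -> CodonUsageTable:
    by_aa: dict[str, list[tuple[str, float]]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace("U", "T").split()
        if len(parts) != 3:
            raise DataError(f"codon table line {lineno}: expected 3 fields")
        codon, aa, frac = parts[0].upper(), parts[1].upper(), float(parts[2])
        if len(codon) != 3 or not set(codon) <= _DNA:
            raise DataError(f"codon table line {lineno}: bad codon {codon!r}")
        if frac < 0:
            raise DataError(f"codon table line {lineno}: negative fraction")
        by_aa.setdefault(aa, []).append((codon, frac))
    sense = {c for aa, lst in by_aa.items() if aa != "*" for c, _ in lst}
    if len(sense) != 61:
        raise DataError(f"codon table covers {len(sense)} sense codons, need 61")
    missing = set(AA_ALPHABET) - set(by_aa)
    if missing:
        raise DataError(f"codon table missing amino acids: {sorted(missing)}")
    norm: dict[str, tuple[tuple[str, float], ...]] = {}
    for aa, lst in by_aa.items():
        total = sum(f for _, f in lst)
        if total <= 0:
            raise DataError(f"amino acid {aa!r} has zero total usage")
        norm[aa] = tuple((c, f / total) for c, f in lst)
    stops = norm.pop("*", ())
    return CodonUsageTable(norm, stops)


def read_codon_table(path) -> CodonUsageTable:
    with open(path) as fh:
        return parse_codon_table(fh.read())


def load_sf9_table() -> CodonUsageTable:
    text = resources.files("depolkit.data").joinpath("sf9.cut").read_text()
    return parse_codon_table(text)


def reverse_translate(
    protein: str,
    table: CodonUsageTable | None = None,
    mode: str = "top",
    seed: int | None = None,
) -> str:
    """DNA coding sequence for ``protein``.

    mode='top' picks the most used codon per residue (deterministic);
    mode='sample' draws each codon with probability equal to its usage
    fraction, reproducibly under ``seed``.
    """
    if table is None:
        table = load_sf9_table()
    if mode not in ("top", "sample"):
        raise DataError(f"unknown mode {mode!r}")
    bad = [c for c in protein if c not in AA_ALPHABET]
    if bad:
        raise DataError(
            f"protein contains non-standard residues: {sorted(set(bad))}"
        )
    if mode == "top":
        return "".join(table.top_codon(aa) for aa in protein)
    rng = np.random.default_rng(seed)
    out = []
    for aa in protein:
        options = table.codons.get(aa)
        if not options:
            raise DataError(f"amino acid {aa!r} absent from codon table")
        codons = [c for c, _ in options]
        probs = np.array([f for _, f in options])
        out.append(codons[rng.choice(len(codons), p=probs / probs.sum())])
    return "".join(out)


def translate(dna: str) -> str:
    """Standard-genetic-code translation (Biopython)."""
    if len(dna) % 3:
        raise DataError("coding sequence length is not a multiple of 3")
    return str(Seq(dna).translate())
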