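"""Consensus binding-site scanning and in-silico enhancer mutagenesis.

Degenerate (IUPAC) consensus patterns such as the Su(H) site ``RTGRGAR`` or the
Run core ``ACCGCA`` are matched exhaustively against an enhancer sequence on
one or both strands, and mutant enhancer variants are constructed by exact
substring substitution, mirroring how reporter constructs are designed for
site-directed mutagenesis (capitalized bases changed, ``-`` deleting a base).

Coordinates are 0-based, half-open, on the forward strand; human-readable
output additionally carries 1-based display coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "EnhancerSequence",
    "ConsensusPattern",
    "MotifHit",
    "SubstitutionSpec",
    "AppliedEdit",
    "scan_consensus",
    "apply_substitutions",
    "build_construct_report",
    "hits_to_frame",
    "hits_to_bed",
    "load_sog_distal",
    "load_packaged_constructs",
    "load_construct_file",
]

# IUPAC nucleotide codes -> the set of bases each one stands for.
IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_VALID_BASES = frozenset("ACGT")


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


@dataclass(frozen=True)
class EnhancerSequence:
    """An enhancer sequence over the strict {A,C,G,T} alphabet.

    Input is case-insensitive; bases are stored uppercase. Ambiguity codes and
    gaps are rejected: a reporter construct is a concrete DNA molecule.
    """

    name: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains non-ACGT characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "EnhancerSequence":
        """Read the first record of a FASTA file."""
        record = next(SeqIO.parse(str(path), "fasta"), None)
        if record is None:
            raise ValueError(f"no FASTA record in {path}")
        return cls(name or record.id, str(record.seq))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.bases), 60):
                fh.write(self.bases[i : i + 60] + "\n")


@dataclass(frozen=True)
class ConsensusPattern:
    """A degenerate consensus motif in IUPAC notation (e.g. ``RTGRGAR``)."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        bad = set(self.pattern) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"pattern {self.name!r} has invalid IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, window: str) -> bool:
        """Exact-length match of a concrete ACGT window against the pattern."""
        w = window.upper()
        return len(w) == len(self.pattern) and all(
            b in IUPAC_CODES[p] for b, p in zip(w, self.pattern)
        )


@dataclass(frozen=True, order=True)
class MotifHit:
    """One strand-aware consensus match.

    ``start``/``end`` are 0-based half-open forward-strand coordinates of the
    matched window; ``matched_seq`` is the forward-strand substring (for a
    − strand hit its reverse complement matches the pattern).
    """

    start: int
    strand: str
    end: int
    pattern_name: str
    matched_seq: str


def scan_consensus(
    seq: EnhancerSequence,
    pattern: ConsensusPattern,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Find every position of ``seq`` matching a degenerate consensus.

    Overlapping hits are all reported. When a window matches on both strands
    and is its own reverse complement, it is reported once, on the + strand.
    Hits are sorted by start, then strand (+ before −).
    """
    m = len(pattern)
    if m > len(seq):
        raise ValueError(
            f"pattern {pattern.name!r} (length {m}) is longer than "
            f"sequence {seq.name!r} (length {len(seq)})"
        )
    hits: list[MotifHit] = []
    s = seq.bases
    for i in range(len(s) - m + 1):
        window = s[i : i + m]
        fwd = pattern.matches(window)
        if fwd:
            hits.append(MotifHit(i, "+", i + m, pattern.name, window))
        if both_strands and pattern.matches(_revcomp(window)):
            if fwd and _revcomp(window) == window:
                continue  # palindromic self-match: report once, on +
            hits.append(MotifHit(i, "-", i + m, pattern.name, window))
    return sorted(hits)


@dataclass(frozen=True)
class SubstitutionSpec:
    """One mutagenesis edit: ``original`` (lowercase wild-type substring) is
    replaced by ``replacement``, where capitalized letters are changed bases
    and ``-`` marks a deleted base. ``occurrence`` (1-based) selects which
    occurrence to edit when ``original`` is not unique."""

    original: str
    replacement: str
    occurrence: int | None = None

    def __post_init__(self) -> None:
        if len(self.original) != len(self.replacement):
            raise ValueError(
                f"replacement {self.replacement!r} must have the same length as "
                f"original {self.original!r} ('-' counts as one position)"
            )
        if set(self.original.upper()) - _VALID_BASES:
            raise ValueError(f"original {self.original!r} must be plain ACGT")
        if set(self.replacement.upper()) - (_VALID_BASES | {"-"}):
            raise ValueError(f"replacement {self.replacement!r} must be ACGT or '-'")

    @property
    def result(self) -> str:
        """The replacement with deletions removed, uppercased."""
        return self.replacement.replace("-", "").upper()


@dataclass(frozen=True)
class AppliedEdit:
    """Provenance of one applied substitution (coordinates on the input)."""

    start: int
    end: int
    original: str
    replacement: str


def _locate(spec: SubstitutionSpec, bases: str) -> int:
    """Forward-strand start of the occurrence of ``spec.original`` to edit."""
    target = spec.original.upper()
    starts = [m.start() for m in re.finditer(re.escape(target), bases)]
    if not starts:
        raise ValueError(f"original {spec.original!r} not found in sequence")
    if spec.occurrence is None:
        if len(starts) > 1:
            raise ValueError(
                f"original {spec.original!r} occurs {len(starts)} times; "
                "give an occurrence index"
            )
        return starts[0]
    if not 1 <= spec.occurrence <= len(starts):
        raise ValueError(
            f"occurrence {spec.occurrence} out of range for {spec.original!r} "
            f"({len(starts)} occurrence(s))"
        )
    return starts[spec.occurrence - 1]


def apply_substitutions(
    seq: EnhancerSequence,
    specs: Sequence[SubstitutionSpec],
    name: str | None = None,
) -> tuple[EnhancerSequence, list[AppliedEdit]]:
    """Apply non-overlapping substitutions to a sequence.

    All edit positions are located on the *input* sequence, then applied
    left-to-right, so deletions in one spec cannot shift another spec's
    coordinates. Returns the mutant sequence plus the applied-edit provenance.
    """
    located = sorted(
        (_locate(spec, seq.bases), spec) for spec in specs
    )
    for (a, sa), (b, sb) in zip(located, located[1:]):
        if a + len(sa.original) > b:
            raise ValueError(
                f"overlapping substitutions: {sa.original!r} at {a} and "
                f"{sb.original!r} at {b}"
            )
    out: list[str] = []
    edits: list[AppliedEdit] = []
    cursor = 0
    for start, spec in located:
        out.append(seq.bases[cursor:start])
        out.append(spec.result)
        edits.append(
            AppliedEdit(start, start + len(spec.original), spec.original, spec.replacement)
        )
        cursor = start + len(spec.original)
    out.append(seq.bases[cursor:])
    return EnhancerSequence(name or f"{seq.name}_mut", "".join(out)), edits


def build_construct_report(
    wt: EnhancerSequence,
    constructs: Mapping[str, Sequence[SubstitutionSpec]],
    patterns: Iterable[ConsensusPattern],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Hit counts and coordinates per construct x pattern, wild type included.

    Returns a tidy frame with columns construct, pattern, n_hits, hits
    (semicolon-joined ``start-end(strand)`` in 0-based half-open coordinates),
    and the construct sequence length.
    """
    patterns = list(patterns)
    rows = []
    variants: list[tuple[str, EnhancerSequence]] = [(wt.name, wt)]
    for cname, specs in constructs.items():
        mutant, _ = apply_substitutions(wt, list(specs), name=cname)
        variants.append((cname, mutant))
    for cname, variant in variants:
        for pattern in patterns:
            hits = scan_consensus(variant, pattern, both_strands=both_strands)
            rows.append(
                {
                    "construct": cname,
                    "pattern": pattern.name,
                    "n_hits": len(hits),
                    "hits": ";".join(f"{h.start}-{h.end}({h.strand})" for h in hits),
                    "length_bp": len(variant),
                }
            )
    return pd.DataFrame(rows)


def hits_to_frame(hits: Sequence[MotifHit], seq_name: str) -> pd.DataFrame:
    """Hit table with both 0-based half-open and 1-based display coordinates."""
    return pd.DataFrame(
        {
            "sequence": seq_name,
            "pattern": [h.pattern_name for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "start_1based": [h.start + 1 for h in hits],
            "strand": [h.strand for h in hits],
            "matched_seq": [h.matched_seq for h in hits],
        }
    )


def hits_to_bed(hits: Sequence[MotifHit], seq_name: str, path: str | Path) -> None:
    """Write hits as BED6 (0-based, half-open, strand in column 6)."""
    with open(path, "w") as fh:
        for h in sorted(hits):
            fh.write(
                f"{seq_name}\t{h.start}\t{h.end}\t{h.pattern_name}\t0\t{h.strand}\n"
            )


def _data_path(filename: str):
    return resources.files("ms2quant.data").joinpath(filename)


def load_sog_distal() -> EnhancerSequence:
    """The packaged 658-bp wild-type sog_Distal enhancer sequence."""
    with resources.as_file(_data_path("sog_distal.fa")) as p:
        return EnhancerSequence.from_fasta(p, name="sog_Distal")


def load_construct_file(
    path: str | Path,
) -> tuple[dict[str, list[SubstitutionSpec]], list[ConsensusPattern]]:
    """Parse a constructs YAML file into substitution specs and patterns."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    patterns = [ConsensusPattern(n, p) for n, p in raw.get("patterns", {}).items()]
    constructs = {
        cname: [
            SubstitutionSpec(
                d["original"], d["replacement"], d.get("occurrence")
            )
            for d in specs
        ]
        for cname, specs in raw.get("constructs", {}).items()
    }
    return constructs, patterns


def load_packaged_constructs() -> tuple[dict[str, list[SubstitutionSpec]], list[ConsensusPattern]]:
    """The packaged sog_Distal mutant-construct table and consensus patterns."""
    with resources.as_file(_data_path("constructs.yaml")) as p:
        return load_construct_file(p)
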