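"""PROSITE-style signature patterns and conservation profiling.

The ZIFL transporter family carries five short diagnostic signatures:
a cysteine motif C-[PS]-G-C in the N-terminal cytoplasmic loop, a
histidine motif [PQ]-E-[TS]-[LI]-H-x-[HKLRD] (most-conserved core
P-E-T-L-H-x-H) in the loop between TM6 and TM7, the canonical MFS
signature G-x(3)-D-[RK]-x-G-R-[RK] -- preceded in this family by a
conserved tryptophan -- the antiporter signature
S-x(8)-G-x(3)-G-P-x(2)-G-G in TM5, and a TM8-TM9 loop motif
[RK]-x(2)-G-P-[IV]-x(3)-R. This module parses such patterns, scans
protein sequences with a configurable substitution tolerance, and
profiles alignment conservation to delimit the family's central
variable region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sequtils import PROTEIN_LETTERS

_ELEMENT_RE = re.compile(r"^(?:(?P<res>[A-Z])|\[(?P<cls>[A-Z]*)\]|x(?:\((?P<n>\d+)\))?)$")


class PatternSyntaxError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    """A parsed signature pattern.

    ``positions`` is the expanded per-position representation: one entry
    per matched residue, each either a frozenset of allowed residues or
    None for a wildcard.
    """

    name: str
    positions: tuple[Optional[frozenset], ...]
    source_text: str

    def __len__(self) -> int:
        return len(self.positions)

    def to_text(self) -> str:
        """Canonical dash-separated pattern text (runs of wildcards re-folded)."""
        parts: list[str] = []
        i = 0
        pos = self.positions
        while i < len(pos):
            p = pos[i]
            if p is None:
                j = i
                while j < len(pos) and pos[j] is None:
                    j += 1
                run = j - i
                parts.append("x" if run == 1 else f"x({run})")
                i = j
            else:
                letters = "".join(sorted(p))
                parts.append(letters if len(letters) == 1 else f"[{letters}]")
                i += 1
        return "-".join(parts)


@dataclass(frozen=True)
class MatchResult:
    pattern: str
    position: int          # 1-based start in the sequence
    span: str
    substitutions: int


def parse_pattern(text: str, name: str = "") -> MotifPattern:
    """Parse a dash-separated pattern: residue | [class] | x | x(n)."""
    positions: list[Optional[frozenset]] = []
    for element in text.split("-"):
        m = _ELEMENT_RE.match(element)
        if not m:
            raise PatternSyntaxError(f"bad pattern element {element!r} in {text!r}")
        if m.group("res"):
            res = m.group("res")
            if res not in PROTEIN_LETTERS:
                raise PatternSyntaxError(f"invalid residue {res!r} in {text!r}")
            positions.append(frozenset(res))
        elif m.group("cls") is not None:
            cls = m.group("cls")
            if not cls:
                raise PatternSyntaxError(f"empty residue class in {text!r}")
            bad = set(cls) - set(PROTEIN_LETTERS)
            if bad:
                raise PatternSyntaxError(f"invalid residues {sorted(bad)} in {text!r}")
            positions.append(frozenset(cls))
        else:
            n = int(m.group("n")) if m.group("n") else 1
            if n < 1:
                raise PatternSyntaxError(f"wildcard repeat must be >= 1 in {text!r}")
            positions.extend([None] * n)
    if not positions:
        raise PatternSyntaxError("empty pattern")
    return MotifPattern(name=name or text, positions=tuple(positions), source_text=text)


def scan_pattern(pattern: MotifPattern, seq: str, max_substitutions: int = 0) -> list[MatchResult]:
    """All windows violating at most ``max_substitutions`` pattern positions.

    Wildcard positions never count as substitutions; matches may overlap
    and are reported in ascending order of start position.
    """
    if max_substitutions < 0:
        raise ValueError("max_substitutions must be >= 0")
    L = len(pattern)
    hits = []
    for start in range(len(seq) - L + 1):
        subs = 0
        for offset, allowed in enumerate(pattern.positions):
            if allowed is not None and seq[start + offset] not in allowed:
                subs += 1
                if subs > max_substitutions:
                    break
        else:
            hits.append(MatchResult(pattern.name, start + 1, seq[start:start + L], subs))
    return hits


# ---------------------------------------------------------------------------
# built-in family signatures

_BUILTIN_TEXT = {
    "cys": "C-[PS]-G-C",
    "his": "[PQ]-E-[TS]-[LI]-H-x-[HKLRD]",
    "his_core": "P-E-T-L-H-x-H",
    "mfs": "G-x(3)-D-[RK]-x-G-R-[RK]",
    "mfs_w": "W-G-x(3)-D-[RK]-x-G-R-[RK]",
    "antiporter": "S-x(8)-G-x(3)-G-P-x(2)-G-G",
    "loop_tm8_tm9": "[RK]-x(2)-G-P-[IV]-x(3)-R",
}

BUILTIN_SIGNATURES: dict[str, MotifPattern] = {
    name: parse_pattern(text, name) for name, text in _BUILTIN_TEXT.items()
}

#: Consensus amino-acid strings of the 14 conserved motifs shared by rice
#: ZIFL proteins (motifs 1-11 plus the variable-region motifs A-C). The
#: family's Cys signature lies inside motif 8 and the His signature inside
#: motif 2.
RICE_ZIFL_MOTIF_CONSENSUS: dict[str, str] = {
    "1": "NWPLMSSIILYCVFSFHDMAYSEIFSLWAESDRKYGGLSFSSEDVGQVLA",
    "2": "QPAEKYPNVFSEKSIFGRFPYFLPCLCISVFAAVVLISCIWLPETLHKHK",
    "3": "LPISSLFPFLYFMIRDLHVAKREEDIGFYAGFVGASYMIGR",
    "4": "LQNNAVPQDQRGTANGIATTAMSFFKAIAPAGAGVLFSWAQKRQHAAFFP",
    "5": "GASLLVYQLFIYPWVHKVLGPINSSRIAAILSIPILCTYPFMTHLSGPWL",
    "6": "RFLLGALNGMLGPIKAYSIEVCRPEHQALGLSIVSTAWGIGLVVGPAIGG",
    "7": "PVIVFSIFSVVIFNTLFGLSTKYWMAITT",
    "8": "HDGCPGCAMERRKEEHKGIPY",
    "9": "ASIFWGIVADRIGRK",
    "10": "GDQMVFFMLNVTEVIGLMLTFKPFLAVP",
    "11": "VLNIASMMKNNLAVTIITGTN",
    "A": "NSVEALEEHLMDPNEEENENE",
    "B": "IKRIKELPSQQAYWD",
    "C": "EELEAQVGGSN",
}


def load_patterns(path) -> dict[str, MotifPattern]:
    """Load patterns from a text file, one "name<TAB>pattern" per line."""
    patterns = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, text = line.partition("\t")
            patterns[name] = parse_pattern(text.strip(), name)
    return patterns


def classify_signatures(
    proteins: Sequence,
    signature_set: Optional[dict[str, MotifPattern]] = None,
    one_sub_signatures: tuple[str, ...] = ("his_core",),
) -> pd.DataFrame:
    """Per-protein, per-signature presence classification.

    A signature is "strict" when a zero-substitution match exists and
    "one_sub" when the best match violates exactly one non-wildcard
    position -- the relaxed class is only evaluated for the signatures
    named in ``one_sub_signatures`` (by default the His core, the one
    signature for which single substitutions are tolerated in family
    practice). Returns a tidy frame (protein, signature, klass, position).
    """
    if signature_set is None:
        signature_set = BUILTIN_SIGNATURES
    rows = []
    for rec in proteins:
        seq = rec.sequence.replace("-", "")
        for name, pattern in signature_set.items():
            tol = 1 if name in one_sub_signatures else 0
            hits = scan_pattern(pattern, seq, max_substitutions=tol)
            if not hits:
                rows.append((rec.id, name, "absent", 0))
                continue
            best = min(hits, key=lambda h: (h.substitutions, h.position))
            klass = "strict" if best.substitutions == 0 else "one_sub"
            rows.append((rec.id, name, klass, best.position))
    return pd.DataFrame(rows, columns=["protein", "signature", "klass", "position"])


# ---------------------------------------------------------------------------
# conservation profiling


@dataclass
class ConservationProfile:
    scores: np.ndarray        # per-column modal-residue frequency in [0, 1]
    smoothed: np.ndarray
    gap_fraction: np.ndarray
    window: int


def conservation_profile(msa: Sequence, window: int = 5) -> ConservationProfile:
    """Per-column conservation = frequency of the modal residue among
    non-gap rows; columns that are >50% gaps score 0. Smoothing is a
    centered moving average (window must be odd)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    lengths = {len(r.sequence) for r in msa}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    arr = np.array([list(r.sequence) for r in msa])
    n_rows, n_cols = arr.shape
    scores = np.zeros(n_cols)
    gap_fraction = np.zeros(n_cols)
    for j in range(n_cols):
        col = arr[:, j]
        nongap = col[col != "-"]
        gap_fraction[j] = 1 - len(nongap) / n_rows
        if gap_fraction[j] > 0.5 or len(nongap) == 0:
            scores[j] = 0.0
        else:
            _, counts = np.unique(nongap, return_counts=True)
            scores[j] = counts.max() / len(nongap)
    half = window // 2
    padded = np.pad(scores, half, mode="edge")
    kernel = np.ones(window) / window
    smoothed = np.convolve(padded, kernel, mode="valid")
    return ConservationProfile(scores, smoothed, gap_fraction, window)


def find_variable_region(
    profile: ConservationProfile, threshold: float = 0.5, min_length: int = 10
) -> Optional[tuple[int, int]]:
    """Longest run of smoothed conservation < threshold with length >=
    min_length, as a 1-based inclusive column interval; leftmost run wins
    ties; None when no qualifying run exists."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    low = profile.smoothed < threshold
    best = None
    start = None
    for i, flag in enumerate(np.append(low, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            run = (start, i - 1)
            if i - start >= min_length and (best is None or (run[1] - run[0]) > (best[1] - best[0])):
                best = run
            start = None
    if best is None:
        return None
    return best[0] + 1, best[1] + 1
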