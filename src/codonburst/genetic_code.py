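"""Standard genetic code, kept as injectable data so alternates can be added."""

from __future__ import annotations

BASES = "ACGT"

# transition partners; every other base pair is a transversion
_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

STANDARD_CODE: dict[str, str] = {}
_AA = (
    "KNKN" "TTTT" "RSRS" "IIMI"  # A--
    "QHQH" "PPPP" "RRRR" "LLLL"  # C--
    "EDED" "AAAA" "GGGG" "VVVV"  # G--
    "*Y*Y" "SSSS" "*CWC" "LFLF"  # T--
)
_i = 0
for _b1 in BASES:
    for _b2 in BASES:
        for _b3 in BASES:
            STANDARD_CODE[_b1 + _b2 + _b3] = _AA[_i]
            _i += 1
del _i, _b1, _b2, _b3

STOP_CODONS = frozenset(c for c, aa in STANDARD_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in STANDARD_CODE if c not in STOP_CODONS))


def translate(codon: str, code: dict[str, str] | None = None) -> str:
    """Amino acid (one-letter) for a codon; '*' for stop."""
    return (code or STANDARD_CODE)[codon.upper()]


def is_stop(codon: str, code: dict[str, str] | None = None) -> bool:
    return translate(codon, code) == "*"


def is_transition(b1: str, b2: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine changes."""
    return (b1, b2) in _TRANSITION


def translate_sequence(seq: str, code: dict[str, str] | None = None) -> str:
    """Translate an in-frame nucleotide sequence; gap/N codons become 'X'."""
    code = code or STANDARD_CODE
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3].upper()
        out.append(code.get(codon, "X") if set(codon) <= set(BASES) else "X")
    return "".join(out)
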