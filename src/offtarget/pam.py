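"""PAM (protospacer adjacent motif) patterns: parsing, matching, dereferencing.

A PAM pattern is a short string over ``{A, C, G, T, N, R}`` that must lie
immediately 3' of a 20-nt protospacer for Cas recognition. Fixed positions
(A/C/G/T) must match literally; N matches any base and R matches a purine
(A or G). Positions that are not a single fixed base are "unspecified": the
concrete genomic base found there is captured (2 bits each) so the fully
dereferenced PAM instance can be reported for every site.
"""

from __future__ import annotations

from dataclasses import dataclass

from .encoding import NUCLEOTIDES

#: Symbols with a fixed base requirement map to themselves; ambiguity symbols
#: map to their allowed base set.
_SYMBOL_SETS = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "N": "ACGT",
    "R": "AG",
}

#: The built-in patterns, registered with fixed ids 0..3 in this order so that
#: serialized indexes are self-describing.
BUILTIN_PAM_TEXTS = ("NGG", "NAG", "NNNNACA", "NNGRRT")

MAX_PAMS = 8  # 3-bit pam_id


class PamPatternError(ValueError):
    """A PAM pattern string is malformed."""


@dataclass(frozen=True)
class PamPattern:
    """A parsed PAM pattern with its table id."""

    text: str
    pam_id: int
    unspecified_positions: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class PamCapture:
    """The concrete bases observed at a pattern's unspecified positions."""

    pam_id: int
    bases: str


def parse_pam(text: str, pam_id: int = 0) -> PamPattern:
    """Parse a PAM pattern string over {A,C,G,T,N,R}.

    Every position whose symbol is not a single fixed base (i.e. N or R) is
    recorded as unspecified; its concrete base is stored per site so the PAM
    can be dereferenced later. Only N and R are accepted: all supported Cas
    variants' motifs (NGG, NAG, NNNNACA, NNGRRT) need no other symbol, and
    rejecting the rest loudly beats silently mis-matching them.
    """
    if not text:
        raise PamPatternError("empty PAM pattern")
    text = text.upper()
    bad = sorted(set(text) - set(_SYMBOL_SETS))
    if bad:
        raise PamPatternError(
            f"illegal PAM symbol(s) {bad!r} in {text!r}; allowed: A C G T N R"
        )
    if not 0 <= pam_id < MAX_PAMS:
        raise PamPatternError(f"pam_id {pam_id} out of range 0..{MAX_PAMS - 1}")
    unspecified = tuple(i for i, s in enumerate(text) if s not in NUCLEOTIDES)
    return PamPattern(text=text, pam_id=pam_id, unspecified_positions=unspecified)


def builtin_pams() -> list[PamPattern]:
    """The four built-in patterns with their stable ids 0..3."""
    return [parse_pam(t, pam_id=i) for i, t in enumerate(BUILTIN_PAM_TEXTS)]


def make_pam_table(texts: list[str] | tuple[str, ...]) -> list[PamPattern]:
    """Build a PAM table from pattern strings.

    Built-in patterns keep their fixed ids 0..3 even when only some are
    requested; user patterns take free ids from 4 upward. At most 8 patterns
    (3-bit id) fit in one index.
    """
    texts = [t.upper() for t in texts]
    if len(set(texts)) != len(texts):
        raise PamPatternError("duplicate PAM pattern in table")
    table: list[PamPattern] = []
    next_free = len(BUILTIN_PAM_TEXTS)
    for t in texts:
        if t in BUILTIN_PAM_TEXTS:
            table.append(parse_pam(t, pam_id=BUILTIN_PAM_TEXTS.index(t)))
        else:
            if next_free >= MAX_PAMS:
                raise PamPatternError(
                    f"too many PAM patterns: at most {MAX_PAMS} per index"
                )
            table.append(parse_pam(t, pam_id=next_free))
            next_free += 1
    if not table:
        raise PamPatternError("at least one PAM pattern is required")
    return table


def pam_match(window: str, pattern: PamPattern) -> PamCapture | None:
    """Match a genomic window against a pattern; capture unspecified bases.

    Returns None when any position fails its symbol's base set, including
    when the window contains N (an undetermined reference base can never be
    asserted to satisfy the motif).
    """
    if len(window) != pattern.length:
        raise ValueError(
            f"window length {len(window)} != pattern length {pattern.length}"
        )
    for base, symbol in zip(window, pattern.text):
        if base not in _SYMBOL_SETS[symbol]:
            return None
    bases = "".join(window[i] for i in pattern.unspecified_positions)
    return PamCapture(pam_id=pattern.pam_id, bases=bases)


def dereference_pam(capture: PamCapture, pattern: PamPattern) -> str:
    """Fill a pattern's unspecified positions with the captured bases.

    The result is the concrete PAM instance present at the site; matching it
    against the pattern again re-captures the same bases.
    """
    if capture.pam_id != pattern.pam_id:
        raise ValueError(
            f"capture pam_id {capture.pam_id} != pattern pam_id {pattern.pam_id}"
        )
    if len(capture.bases) != len(pattern.unspecified_positions):
        raise ValueError(
            f"capture has {len(capture.bases)} bases but pattern {pattern.text!r} "
            f"has {len(pattern.unspecified_positions)} unspecified positions"
        )
    out = list(pattern.text)
    for pos, base in zip(pattern.unspecified_positions, capture.bases):
        if base not in _SYMBOL_SETS[pattern.text[pos]]:
            raise ValueError(
                f"captured base {base!r} inconsistent with symbol "
                f"{pattern.text[pos]!r} at position {pos}"
            )
        out[pos] = base
    return "".join(out)
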