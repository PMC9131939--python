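"""Seed-sequence target scanning: canonical site patterns, KMP search, site
classification, and simplified context features.

The seed of a mature miRNA is nucleotides 2-8 (5'->3').  On the UTR sense
strand the canonical site classes are:

* 7mer-m8: reverse complement of positions 2-8
* 8mer:    7mer-m8 followed by an A (opposite miRNA position 1)
* 7mer-A1: reverse complement of positions 2-7, followed by an A
* 6mer:    reverse complement of positions 2-7

Matching is exact-complementarity string search via the Knuth-Morris-Pratt
automaton (the prefix function is exposed for testing).  Overlapping hits
resolve by type precedence 8mer > 7mer-m8 > 7mer-A1 > 6mer, stronger types
consuming their window; coordinates are 1-based inclusive ("Position a-b"
style).  6mer sites are only reported when explicitly requested.

``simple_context_score`` is an explicitly simplified, fixed-weight surrogate
for trained context scores: it combines site type, local AU content,
3'-supplementary pairing and distance to the nearest UTR end so that, for
identical context, 8mer < 7mer-m8 < 7mer-A1 < 6mer (more negative =
stronger).  Its numeric values are NOT comparable to published trained
context scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_PRECEDENCE = {t: i for i, t in enumerate(SITE_TYPES)}

# fixed surrogate weights; type weights reproduce the canonical strength order
W_TYPE = {"8mer": -0.31, "7mer-m8": -0.16, "7mer-A1": -0.10, "6mer": -0.03}
W_AU = -0.06
W_3P = -0.03
W_DIST = +0.05
AU_FLANK = 30
DIST_CAP = 1500


def _normalize_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


def _revcomp_rna(seq: str) -> str:
    # complement via Biopython's DNA table, then back to the RNA alphabet
    return reverse_complement(seq.replace("U", "T")).replace("T", "U")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA; T on input is normalized to U, length must be >= 8."""
    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize_rna(self.sequence))
        if len(self.sequence) < 8:
            raise ValueError("mature miRNA must be at least 8 nt")


@dataclass
class SeedSite:
    """A classified binding site; start/end are 1-based inclusive UTR coords."""
    transcript: str
    start: int
    end: int
    site_type: str
    features: dict = field(default_factory=dict)
    simple_context_score: float | None = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start + 1 != len_of(self.site_type):
            raise ValueError("site length does not match its type")

    @property
    def position_label(self) -> str:
        return f"{self.start}-{self.end}"


def len_of(site_type: str) -> int:
    return {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[site_type]


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

def seed_patterns(mirna: MatureMiRNA) -> dict[str, str]:
    """UTR-sense search pattern (RNA alphabet) for each canonical site type."""
    seq = mirna.sequence
    seed_2_8 = seq[1:8]
    seed_2_7 = seq[1:7]
    m8 = _revcomp_rna(seed_2_8)
    six = _revcomp_rna(seed_2_7)
    return {
        "8mer": m8 + "A",
        "7mer-m8": m8,
        "7mer-A1": six + "A",
        "6mer": six,
    }


# ---------------------------------------------------------------------------
# KMP
# ---------------------------------------------------------------------------

def prefix_function(pattern: str) -> list[int]:
    """Longest proper border length for every prefix of ``pattern``."""
    pi = [0] * len(pattern)
    k = 0
    for i in range(1, len(pattern)):
        while k > 0 and pattern[i] != pattern[k]:
            k = pi[k - 1]
        if pattern[i] == pattern[k]:
            k += 1
        pi[i] = k
    return pi


def kmp_search(pattern: str, text: str) -> list[int]:
    """All (possibly overlapping) 1-based occurrences of ``pattern`` in
    ``text``; case-insensitive, U and T equivalent."""
    if not pattern:
        raise ValueError("empty pattern")
    p = pattern.upper().replace("T", "U")
    t = text.upper().replace("T", "U")
    pi = prefix_function(p)
    hits = []
    k = 0
    for i, c in enumerate(t):
        while k > 0 and c != p[k]:
            k = pi[k - 1]
        if c == p[k]:
            k += 1
        if k == len(p):
            hits.append(i - len(p) + 2)   # 1-based start
            k = pi[k - 1]
    return hits


# ---------------------------------------------------------------------------
# scanning and features
# ---------------------------------------------------------------------------

def scan_utr(mirna: MatureMiRNA, utr: str, transcript: str = "utr",
             include_6mer: bool = False, with_features: bool = True) -> list[SeedSite]:
    """Scan one UTR for canonical seed sites.

    All four patterns are searched via KMP; overlapping candidates resolve
    by type precedence (then leftmost start), stronger types consuming their
    window.  6mers are reported only when ``include_6mer`` is set.
    """
    text = utr.upper().replace("T", "U")
    if len(text) < 6:
        return []
    patterns = seed_patterns(mirna)
    candidates = []
    for site_type in SITE_TYPES:
        for start in kmp_search(patterns[site_type], text):
            candidates.append((SITE_PRECEDENCE[site_type], start, site_type))
    candidates.sort()
    accepted: list[SeedSite] = []
    occupied: list[tuple[int, int]] = []
    for _, start, site_type in candidates:
        end = start + len_of(site_type) - 1
        if any(start <= e and end >= s for s, e in occupied):
            continue
        occupied.append((start, end))
        accepted.append(SeedSite(transcript=transcript, start=start, end=end,
                                 site_type=site_type))
    if not include_6mer:
        accepted = [s for s in accepted if s.site_type != "6mer"]
    accepted.sort(key=lambda s: s.start)
    if with_features:
        for site in accepted:
            context_features(site, mirna, text)
    return accepted


def scan_fasta(mirna: MatureMiRNA, records, include_6mer: bool = False) -> list[SeedSite]:
    """Scan a collection of Biopython SeqRecords (or {id: seq} dict)."""
    if isinstance(records, dict):
        items = records.items()
    else:
        items = [(r.id, str(r.seq)) for r in records]
    sites: list[SeedSite] = []
    for name, seq in items:
        sites.extend(scan_utr(mirna, str(seq), transcript=name,
                              include_6mer=include_6mer))
    return sites


def _pairs(a: str, b: str) -> bool:
    return {a, b} in ({"A", "U"}, {"G", "C"})


def context_features(site: SeedSite, mirna: MatureMiRNA, utr: str) -> SeedSite:
    """Attach local AU content, UTR-end distance, 3'-supplementary pairing
    and the simple context score to ``site`` (modified in place, returned).

    Local AU = A/U fraction of the 30 nt flanking each side (truncated at
    the UTR ends).  Distance = min(start-1, L-end).  3'-supplementary
    pairing = longest contiguous Watson-Crick run between miRNA positions
    13-16 and the UTR stretch immediately 5' of the site (opposite them).
    """
    text = utr.upper().replace("T", "U")
    L = len(text)
    if not (1 <= site.start <= site.end <= L):
        raise ValueError("site coordinates overflow the UTR")
    s0, e0 = site.start - 1, site.end          # 0-based half-open
    flank = text[max(0, s0 - AU_FLANK):s0] + text[e0:e0 + AU_FLANK]
    au = sum(c in "AU" for c in flank) / len(flank) if flank else 0.0
    distance = min(site.start - 1, L - site.end)

    # miRNA 13-16 pairs the UTR just 5' of the seed site, antiparallel
    mir_13_16 = mirna.sequence[12:16]
    opp = text[max(0, s0 - 8):s0][::-1]        # walk 3'->5' away from the site
    best = run = 0
    for i in range(min(len(mir_13_16), len(opp))):
        if _pairs(mir_13_16[i], opp[i]):
            run += 1
            best = max(best, run)
        else:
            run = 0
    score = (W_TYPE[site.site_type] + W_AU * (au - 0.5)
             + W_3P * best / 4.0 + W_DIST * min(distance, DIST_CAP) / DIST_CAP)
    site.features = {"local_au": au, "utr_end_distance": distance,
                     "supplementary_pairing": best}
    site.simple_context_score = score
    return site
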