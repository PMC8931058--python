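"""Canonical miRNA target-site scanning and designed-site verification.

Site classes follow the canonical seed-match convention.  Writing the miRNA
5'→3' and the target 5'→3', with rc() the reverse complement:

* ``6mer``     = rc(miRNA nt 2–7)
* ``7mer-m8``  = rc(miRNA nt 2–8)
* ``7mer-A1``  = rc(miRNA nt 2–7) + A  (an adenosine opposite position 1)
* ``8mer``     = rc(miRNA nt 2–8) + A

Designed sites are additionally checked for perfect Watson–Crick pairing
opposite the seed (nt 2–8) and the 3' supplemental region (nt 13–16) at the
canonical register (the target position opposite miRNA nt j is the j-th base
from the site's 3' end).  The scanner also audits a "cleaned" 3' UTR —
one from which all canonical sites of an abundant-miRNA list were removed —
and reports any residual sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: site-type → length of the matched target substring
SITE_LENGTHS = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}


def _check_rna(seq: str, what: str) -> str:
    seq = seq.upper()
    if "T" in seq:
        warnings.warn(f"{what} contains T; converting to U (DNA input assumed)",
                      stacklevel=3)
        seq = seq.replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"{what} has non-RNA characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MiRNA:
    """A mature miRNA, 5'→3' RNA; ``abundance_rank`` orders an abundance list."""
    name: str
    sequence: str
    abundance_rank: int | None = None

    def __post_init__(self) -> None:
        self.sequence = _check_rna(self.sequence, f"miRNA {self.name}")
        if len(self.sequence) < 16:
            raise ValueError(f"miRNA {self.name}: sequence shorter than 16 nt")


@dataclass
class SeedSite:
    """One canonical site occurrence in a target (0-based, forward strand)."""
    mirna_name: str
    site_type: str
    start: int
    matched_sequence: str

    def __post_init__(self) -> None:
        if len(self.matched_sequence) != SITE_LENGTHS[self.site_type]:
            raise ValueError(f"{self.site_type} site must be "
                             f"{SITE_LENGTHS[self.site_type]} nt")

    @property
    def end(self) -> int:
        return self.start + len(self.matched_sequence)


def seed_match_strings(mirna: MiRNA) -> dict[str, str]:
    """Target-space (5'→3') match strings for each canonical site type."""
    seq = mirna.sequence
    if len(seq) < 8:
        raise ValueError("miRNA too short for seed-match construction")
    rc_2_7 = reverse_complement(seq[1:7])
    rc_2_8 = reverse_complement(seq[1:8])
    return {
        "6mer": rc_2_7,
        "7mer-m8": rc_2_8,
        "7mer-A1": rc_2_7 + "A",
        "8mer": rc_2_8 + "A",
    }


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)  # overlapping occurrences count
    return out


def scan_utr(utr: str, mirnas: list[MiRNA]) -> list[SeedSite]:
    """All canonical site occurrences of each miRNA in a 3' UTR.

    Overlapping hits of the same miRNA are deduplicated longest-type-first:
    a site is suppressed when its interval lies inside a longer-type site of
    the same miRNA (an 8mer therefore reports once, not additionally as the
    7mers/6mer it contains).  Output is sorted by position.
    """
    if not utr:
        return []
    utr = _check_rna(utr, "UTR")
    sites: list[SeedSite] = []
    for mirna in mirnas:
        matches = seed_match_strings(mirna)
        raw: list[SeedSite] = []
        for site_type in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
            for start in _find_all(utr, matches[site_type]):
                raw.append(SeedSite(mirna.name, site_type, start, matches[site_type]))
        keep: list[SeedSite] = []
        for s in raw:
            contained = any(
                SITE_LENGTHS[t.site_type] > SITE_LENGTHS[s.site_type]
                and t.start <= s.start and s.end <= t.end
                for t in raw)
            if not contained:
                keep.append(s)
        sites.extend(keep)
    sites.sort(key=lambda s: (s.start, s.mirna_name, -SITE_LENGTHS[s.site_type]))
    return sites


def verify_site_pairing(site_seq: str, mirna: MiRNA) -> tuple[bool, bool]:
    """Check a designed site for perfect pairing against seed and supplemental.

    ``site_seq`` is the target site 5'→3' and must span positions opposite
    miRNA nt 1–16 (length ≥ 16) at the canonical register: the base opposite
    miRNA nt j is the j-th from the site's 3' end.  Returns
    ``(seed_paired, supplemental_paired)`` — perfect Watson–Crick
    complementarity opposite nt 2–8 and nt 13–16 respectively.
    """
    site_seq = _check_rna(site_seq, "site")
    if len(site_seq) < 16:
        raise ValueError("site must span positions opposite miRNA nt 1-16 "
                         f"(length >= 16, got {len(site_seq)})")
    mir = mirna.sequence

    def _paired(j: int) -> bool:
        return site_seq[-j] == mir[j - 1].translate(_COMPLEMENT)

    seed = all(_paired(j) for j in range(2, 9))
    supplemental = all(_paired(j) for j in range(13, 17))
    return seed, supplemental


def audit_clean_utr(utr: str, mirnas: list[MiRNA]) -> dict:
    """Audit a supposedly site-free UTR against a miRNA list.

    Returns ``{"clean": bool, "n_residual": int, "residual_sites":
    {mirna_name: [SeedSite, ...]}}``; a clean UTR yields an empty mapping.
    The audit is a pure function of its inputs (idempotent).
    """
    residual: dict[str, list[SeedSite]] = {}
    for site in scan_utr(utr, mirnas):
        residual.setdefault(site.mirna_name, []).append(site)
    n = sum(len(v) for v in residual.values())
    return {"clean": n == 0, "n_residual": n, "residual_sites": residual}
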