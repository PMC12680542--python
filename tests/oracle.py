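"""Independent brute-force oracle for single-column consensus calling.

Re-derives flags, silencing, weighting and thresholding from the written
rules with plain tally loops, sharing no code with the implementation. Used
to cross-check ``call_column`` exhaustively on small columns.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class OracleEntry:
    base: str
    orientation: str  # "forward" | "reverse"
    dist5: int
    dist3: int


def oracle_damage_freq(entry: OracleEntry, profile) -> float:
    """Nearer-end profile lookup, written independently."""
    if entry.orientation == "forward":
        near5, near3, fallback = profile.ct5, profile.ct3, profile.baseline_ct
    else:
        near5, near3, fallback = profile.ga5, profile.ga3, profile.baseline_ga
    if entry.dist5 <= entry.dist3:
        dist, arr = entry.dist5, near5
    else:
        dist, arr = entry.dist3, near3
    if dist >= profile.window:
        return fallback
    return float(arr[dist])


def oracle_flags(entries, ref_base, method):
    """(flag_ct, flag_ga) per the polarized or polarization-free rule."""
    fwd_t = any(e.base == "T" and e.orientation == "forward" for e in entries)
    rev_a = any(e.base == "A" and e.orientation == "reverse" for e in entries)
    if method == "polarized":
        return (ref_base == "C" and fwd_t, ref_base == "G" and rev_a)
    any_c = any(e.base == "C" for e in entries)
    any_g = any(e.base == "G" for e in entries)
    return (fwd_t and any_c, rev_a and any_g)


def oracle_call(entries, mode, ref_base, min_cov, min_support, profile=None):
    """Consensus call of one column by exhaustive tally-and-threshold."""
    informative = [e for e in entries if e.base != "N"]

    if mode == "none":
        kept = informative
    elif mode in ("pol_silence", "free_silence"):
        method = "polarized" if mode == "pol_silence" else "polarization_free"
        ct, ga = oracle_flags(informative, ref_base, method)
        kept = []
        for e in informative:
            if ct and e.base == "T" and e.orientation == "forward":
                continue
            if ga and e.base == "A" and e.orientation == "reverse":
                continue
            kept.append(e)
    elif mode == "free_weight":
        tallies = {}
        for e in informative:
            d = min(oracle_damage_freq(e, profile), 0.99)
            if e.orientation == "forward" and e.base == "T":
                w = 1.0 - d
            elif e.orientation == "forward" and e.base == "C":
                w = 1.0 + d
            elif e.orientation == "reverse" and e.base == "A":
                w = 1.0 - d
            elif e.orientation == "reverse" and e.base == "G":
                w = 1.0 + d
            else:
                w = 1.0
            tallies[e.base] = tallies.get(e.base, 0.0) + w
        if len(informative) < min_cov or not tallies:
            return "N"
        total = sum(tallies.values())
        best = max(tallies, key=tallies.get)
        return best if tallies[best] / total >= min_support else "N"
    else:
        raise ValueError(mode)

    if len(kept) < min_cov:
        return "N"
    counts = {}
    for e in kept:
        counts[e.base] = counts.get(e.base, 0) + 1
    best = max(counts, key=counts.get)
    return best if counts[best] / len(kept) >= min_support else "N"
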