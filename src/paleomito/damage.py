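"""Post-mortem damage profile estimation and per-base weights.

Single-stranded ancient-DNA libraries show cytosine deamination as C->T
mismatches on forward-mapping reads and G->A mismatches on reverse-mapping
reads, concentrated at the fragment ends. This module estimates those
misincorporation frequencies per end-distance from a pileup (the in-house
equivalent of a DamageProfiler run), and converts them into multiplicative
weights for the polarization-free weighting consensus mode: a putatively
damaged base is downweighted by ``1 - d`` while its undamaged counterpart at
the same position is upweighted by ``1 + d``, so that a balanced damaged /
undamaged pair keeps the same total mass as two raw observations.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from paleomito.alignio import FORWARD, REVERSE, AlignedRead, PileupColumn, PileupEntry

#: Cap on the damage frequency used to form weights: keeps 1-d strictly
#: positive even when a sparse profile cell estimates d = 1.0.
MAX_WEIGHT_FREQ = 0.99

#: Number of innermost window cells averaged into the beyond-window baseline.
_BASELINE_CELLS = 5


@dataclass
class DamageProfile:
    """Position-specific misincorporation frequencies.

    ``ct5[i]`` is the T-versus-reference-C mismatch rate of forward-mapping
    reads at distance ``i`` from the left (5') alignment end; ``ct3`` the same
    from the right (3') end. ``ga5``/``ga3`` are the A-versus-reference-G rates
    of reverse-mapping reads, indexed the same way. Distances beyond the window
    fall back to ``baseline_ct``/``baseline_ga``. ``n_obs`` holds the per-cell
    denominators under keys ``ct5``/``ct3``/``ga5``/``ga3``.
    """

    window: int
    ct5: np.ndarray
    ct3: np.ndarray
    ga5: np.ndarray
    ga3: np.ndarray
    baseline_ct: float = 0.0
    baseline_ga: float = 0.0
    n_obs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        for name in ("ct5", "ct3", "ga5", "ga3"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.window,):
                raise ValueError(f"{name} must have length window={self.window}")
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} frequencies must lie in [0, 1]")
            setattr(self, name, arr)

    @classmethod
    def zero(cls, window: int = 25) -> "DamageProfile":
        """An all-zero profile: weighting degenerates to plain counting."""
        z = np.zeros(window)
        return cls(window, z.copy(), z.copy(), z.copy(), z.copy())


@dataclass
class FragmentStats:
    """Fragment-length summary of a mapped read set."""

    mean_len: float
    median_len: float
    histogram: dict[int, int]


def estimate_profile(pileup: list[PileupColumn], window: int = 25) -> DamageProfile:
    """Estimate the damage profile from a reference-polarized pileup.

    For each end-distance ``i < window``: ``ct5[i]`` = (# forward entries with
    base T at ``dist5 == i`` on reference-C columns) / (# forward A/C/G/T
    entries at that distance on reference-C columns); ``ct3``, ``ga5``, ``ga3``
    analogous (GA over reverse entries on reference-G columns). Baselines are
    the mean over the innermost five window cells of the corresponding pair of
    arrays; cells with zero denominator inherit the baseline rather than zero,
    so rarely covered distances never look spuriously damage-free.

    Profile estimation is reference-polarized even though two of the calling
    modes are not: only the flagging/calling step is polarization-free.
    """
    if not pileup:
        raise ValueError("cannot estimate a damage profile from an empty pileup")
    num = {k: np.zeros(window) for k in ("ct5", "ct3", "ga5", "ga3")}
    den = {k: np.zeros(window) for k in ("ct5", "ct3", "ga5", "ga3")}
    total_entries = 0
    for col in pileup:
        rb = col.ref_base
        if rb not in ("C", "G"):
            total_entries += len(col.entries)
            continue
        for e in col.entries:
            total_entries += 1
            if e.base == "N":
                continue
            if rb == "C" and e.orientation == FORWARD:
                if e.dist5 < window:
                    den["ct5"][e.dist5] += 1
                    if e.base == "T":
                        num["ct5"][e.dist5] += 1
                if e.dist3 < window:
                    den["ct3"][e.dist3] += 1
                    if e.base == "T":
                        num["ct3"][e.dist3] += 1
            elif rb == "G" and e.orientation == REVERSE:
                if e.dist5 < window:
                    den["ga5"][e.dist5] += 1
                    if e.base == "A":
                        num["ga5"][e.dist5] += 1
                if e.dist3 < window:
                    den["ga3"][e.dist3] += 1
                    if e.base == "A":
                        num["ga3"][e.dist3] += 1
    if total_entries == 0:
        raise ValueError("pileup holds no read bases; cannot estimate a damage profile")

    freqs = {}
    for k in num:
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[k] = np.where(den[k] > 0, num[k] / np.maximum(den[k], 1), np.nan)

    def _baseline(a: np.ndarray, b: np.ndarray) -> float:
        inner = np.concatenate([a[-_BASELINE_CELLS:], b[-_BASELINE_CELLS:]])
        inner = inner[~np.isnan(inner)]
        return float(inner.mean()) if inner.size else 0.0

    baseline_ct = _baseline(freqs["ct5"], freqs["ct3"])
    baseline_ga = _baseline(freqs["ga5"], freqs["ga3"])
    for k, base in (("ct5", baseline_ct), ("ct3", baseline_ct),
                    ("ga5", baseline_ga), ("ga3", baseline_ga)):
        freqs[k] = np.where(np.isnan(freqs[k]), base, freqs[k])

    return DamageProfile(
        window=window,
        ct5=freqs["ct5"],
        ct3=freqs["ct3"],
        ga5=freqs["ga5"],
        ga3=freqs["ga3"],
        baseline_ct=baseline_ct,
        baseline_ga=baseline_ga,
        n_obs={k: den[k] for k in den},
    )


def damage_frequency(entry: PileupEntry, profile: DamageProfile, lookup: str = "nearer") -> float:
    """Damage frequency applicable to a pileup entry's read position.

    With ``lookup="nearer"`` (default) the profile array anchored at the
    nearer alignment end is consulted — appropriate for single-stranded
    libraries, which accumulate deamination at both fragment ends. With
    ``lookup="five_prime"`` only the left-end arrays are used. Positions
    beyond the window return the baseline. Total function: never raises.
    """
    if entry.orientation == FORWARD:
        a5, a3, base = profile.ct5, profile.ct3, profile.baseline_ct
    else:
        a5, a3, base = profile.ga5, profile.ga3, profile.baseline_ga
    if lookup == "five_prime":
        return float(a5[entry.dist5]) if entry.dist5 < profile.window else base
    if entry.dist5 <= entry.dist3:
        return float(a5[entry.dist5]) if entry.dist5 < profile.window else base
    return float(a3[entry.dist3]) if entry.dist3 < profile.window else base


def base_weight(entry: PileupEntry, profile: DamageProfile, lookup: str = "nearer") -> float:
    """Multiplicative weight of one read base under the weighting mode.

    Forward T -> ``1 - d``; forward C -> ``1 + d``; reverse A -> ``1 - d``;
    reverse G -> ``1 + d``; every other base/orientation pair -> 1. ``d`` is
    the entry's damage frequency, capped just below 1 so weights stay
    positive. A column holding one damaged base and its undamaged counterpart
    at the same end-distance therefore keeps total weight 2, matching the raw
    count.
    """
    b, o = entry.base, entry.orientation
    if (o == FORWARD and b in "TC") or (o == REVERSE and b in "AG"):
        d = min(damage_frequency(entry, profile, lookup), MAX_WEIGHT_FREQ)
        if b in "TA":
            return 1.0 - d
        return 1.0 + d
    return 1.0


def fragment_stats(reads: list[AlignedRead]) -> FragmentStats:
    """Mean/median/histogram of mapped fragment lengths."""
    if not reads:
        raise ValueError("cannot compute fragment statistics of an empty read set")
    lengths = np.array([r.length for r in reads])
    return FragmentStats(
        mean_len=float(lengths.mean()),
        median_len=float(np.median(lengths)),
        histogram=dict(sorted(Counter(int(x) for x in lengths).items())),
    )


def save_profile(profile: DamageProfile, tsv_path, json_path=None) -> None:
    """Serialize a profile as TSV (per-distance rows) + JSON sidecar.

    The TSV has one row per end-distance with the four frequency columns and
    their denominators; window size and baselines go to the sidecar (default:
    TSV path with a .json suffix). The format is documented so profiles
    exported from external damage-assessment tools can be imported.
    """
    import pandas as pd

    if json_path is None:
        json_path = str(tsv_path) + ".json"
    df = pd.DataFrame(
        {
            "distance": np.arange(profile.window),
            "ct5": profile.ct5,
            "ct3": profile.ct3,
            "ga5": profile.ga5,
            "ga3": profile.ga3,
            "n_ct5": profile.n_obs.get("ct5", np.zeros(profile.window)).astype(int),
            "n_ct3": profile.n_obs.get("ct3", np.zeros(profile.window)).astype(int),
            "n_ga5": profile.n_obs.get("ga5", np.zeros(profile.window)).astype(int),
            "n_ga3": profile.n_obs.get("ga3", np.zeros(profile.window)).astype(int),
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(
            {
                "window": profile.window,
                "baseline_ct": profile.baseline_ct,
                "baseline_ga": profile.baseline_ga,
                "end_lookup": "nearer",
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def load_profile(tsv_path, json_path=None) -> DamageProfile:
    """Inverse of :func:`save_profile`."""
    import pandas as pd

    if json_path is None:
        json_path = str(tsv_path) + ".json"
    df = pd.read_csv(tsv_path, sep="\t")
    with open(json_path) as fh:
        meta = json.load(fh)
    window = int(meta["window"])
    if len(df) != window:
        raise ValueError(f"profile TSV has {len(df)} rows but sidecar window is {window}")
    return DamageProfile(
        window=window,
        ct5=df["ct5"].to_numpy(float),
        ct3=df["ct3"].to_numpy(float),
        ga5=df["ga5"].to_numpy(float),
        ga3=df["ga3"].to_numpy(float),
        baseline_ct=float(meta["baseline_ct"]),
        baseline_ga=float(meta["baseline_ga"]),
        n_obs={k: df[f"n_{k}"].to_numpy(float) for k in ("ct5", "ct3", "ga5", "ga3")},
    )
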