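"""Triacylglycerol (TAG) quantification and composition analytics.

Species are identified as ``TAG C:D`` by total acyl carbons and total
double bonds, optionally chain-resolved as ``TAG C:D (c1:d1/c2:d2/c3:d3)``.
Quantification is class-level against a single spiked internal standard
of known concentration (response factors assumed 1):

    concentration = intensity / IS_intensity * IS_known_concentration

Composition statistics are molar (quantity-weighted): the double-bond
histogram, the "contains at least one fully saturated chain" class
fraction, the total-carbon chain-length histogram over the 48-58 C
classes, and the DNL index, the ratio of C16:0 to C18:2 chain abundance
in the TAG pool (palmitate is the primary DNL product while linoleate is
strictly dietary, so a high ratio flags endogenous synthesis).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TagSpecies",
    "TagProfile",
    "parse_species_name",
    "quantify",
    "total_tag",
    "total_tag_fold_change",
    "unsaturation_distribution",
    "chain_length_distribution",
    "dnl_index",
    "profile_to_frame",
    "profile_from_frame",
]

CHAIN_LENGTH_CLASSES = (48, 50, 52, 54, 56, 58)

_NAME_RE = re.compile(
    r"^TAG\s+(?P<C>\d+):(?P<D>\d+)"
    r"(?:\s*\(\s*(?P<c1>\d+):(?P<d1>\d+)\s*/\s*(?P<c2>\d+):(?P<d2>\d+)\s*/\s*(?P<c3>\d+):(?P<d3>\d+)\s*\))?\s*$"
)


@dataclass(frozen=True)
class TagSpecies:
    """One TAG species; ``chains`` is None when not chain-resolved."""

    name: str
    total_carbons: int
    total_double_bonds: int
    chains: tuple[tuple[int, int], ...] | None = None
    intensity: float | None = None
    quantity: float | None = None  # pmol, filled in by quantify()


@dataclass(frozen=True)
class TagProfile:
    """A set of TAG species from one condition plus the internal standard."""

    condition: str
    species: tuple[TagSpecies, ...]
    internal_standard: tuple[float, float]  # (intensity, known concentration pmol)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique within a profile")


def parse_species_name(text: str) -> TagSpecies:
    """Parse ``TAG C:D`` or ``TAG C:D (c1:d1/c2:d2/c3:d3)`` into a skeleton.

    Chain-resolved names are validated against the stated totals.
    """
    m = _NAME_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed TAG species name: {text!r}")
    total_c, total_d = int(m["C"]), int(m["D"])
    chains = None
    if m["c1"] is not None:
        chains = tuple(
            (int(m[f"c{i}"]), int(m[f"d{i}"])) for i in (1, 2, 3)
        )
        c_sum = sum(c for c, _ in chains)
        d_sum = sum(d for _, d in chains)
        if c_sum != total_c:
            raise ValueError(
                f"inconsistent species name {text!r}: chain carbons sum to {c_sum} != {total_c}"
            )
        if d_sum != total_d:
            raise ValueError(
                f"inconsistent species name {text!r}: chain double bonds sum to {d_sum} != {total_d}"
            )
    return TagSpecies(text.strip(), total_c, total_d, chains)


def quantify(profile: TagProfile) -> TagProfile:
    """Convert species intensities to pmol via the internal standard."""
    is_intensity, is_conc = profile.internal_standard
    if is_intensity <= 0:
        raise ValueError("internal-standard intensity must be positive")
    new_species = []
    for s in profile.species:
        if s.intensity is None:
            raise ValueError(f"species {s.name!r} has no intensity to quantify")
        new_species.append(replace(s, quantity=s.intensity / is_intensity * is_conc))
    return replace(profile, species=tuple(new_species))


def _quantities(profile: TagProfile) -> np.ndarray:
    q = [s.quantity for s in profile.species]
    if any(v is None for v in q):
        raise ValueError("profile is not quantified; call quantify() first")
    return np.asarray(q, dtype=float)


def total_tag(profile: TagProfile) -> float:
    """Summed TAG quantity (pmol) over all species."""
    return float(_quantities(profile).sum())


def total_tag_fold_change(profile_a: TagProfile, profile_b: TagProfile) -> float:
    """Total TAG of ``profile_a`` relative to ``profile_b``."""
    denom = total_tag(profile_b)
    if denom <= 0:
        raise ValueError("reference profile has zero total TAG")
    return total_tag(profile_a) / denom


def unsaturation_distribution(profile: TagProfile) -> tuple[pd.Series, float]:
    """Quantity-weighted unsaturation views of a profile.

    Returns ``(by_double_bonds, saturated_chain_fraction)`` where the
    series maps total double bonds to molar fraction (sums to 1) and the
    float is the fraction of TAG carrying at least one fully saturated
    constituent chain (computed over chain-resolved species only).
    """
    q = _quantities(profile)
    total = q.sum()
    if total <= 0:
        raise ValueError("profile has zero total quantity")
    db = pd.Series(q, index=[s.total_double_bonds for s in profile.species])
    by_db = db.groupby(level=0).sum() / total
    by_db.index.name = "total_double_bonds"

    resolved = [(s, w) for s, w in zip(profile.species, q) if s.chains is not None]
    if len(resolved) < len(profile.species):
        warnings.warn(
            "species without chain resolution contribute only to the double-bond view",
            stacklevel=2,
        )
    if not resolved:
        return by_db, float("nan")
    res_total = sum(w for _, w in resolved)
    sat = sum(w for s, w in resolved if any(d == 0 for _, d in s.chains))
    return by_db, float(sat / res_total)


def chain_length_distribution(
    profile: TagProfile, classes: Sequence[int] = CHAIN_LENGTH_CLASSES
) -> pd.Series:
    """Quantity-weighted total-carbon class fractions (sum to 1).

    Species outside the class range are binned to the nearest boundary
    class with a warning.
    """
    if not profile.species:
        raise ValueError("empty profile")
    q = _quantities(profile)
    total = q.sum()
    if total <= 0:
        raise ValueError("profile has zero total quantity")
    classes = tuple(sorted(classes))
    frac = pd.Series(0.0, index=pd.Index(classes, name="total_carbons"))
    clipped = False
    for s, w in zip(profile.species, q):
        c = s.total_carbons
        if c < classes[0]:
            c, clipped = classes[0], True
        elif c > classes[-1]:
            c, clipped = classes[-1], True
        elif c not in classes:
            # odd-carbon or off-grid totals go to the closest class
            c = min(classes, key=lambda k: abs(k - s.total_carbons))
        frac[c] += w / total
    if clipped:
        warnings.warn("species outside the chain-length class range were binned to the boundary", stacklevel=2)
    return frac


def dnl_index(profile: TagProfile) -> float:
    """C16:0 / C18:2 chain abundance ratio of the TAG pool.

    Both counts are quantity-weighted over chain-resolved species; the
    index is undefined (error) when the pool contains no C18:2 chains.
    """
    q = _quantities(profile)
    c160 = c182 = 0.0
    for s, w in zip(profile.species, q):
        if s.chains is None:
            continue
        c160 += w * sum(1 for ch in s.chains if ch == (16, 0))
        c182 += w * sum(1 for ch in s.chains if ch == (18, 2))
    if c182 <= 0:
        raise ValueError("DNL index undefined: no C18:2 chains in profile")
    return float(c160 / c182)


def profile_to_frame(profile: TagProfile) -> pd.DataFrame:
    """Tidy frame with the internal standard flagged by ``is_standard=1``."""
    rows = []
    for s in profile.species:
        rows.append(
            {
                "condition": profile.condition,
                "tag_name": s.name,
                "intensity": s.intensity,
                "quantity_pmol": s.quantity,
                "is_standard": 0,
                "known_conc_pmol": np.nan,
            }
        )
    is_int, is_conc = profile.internal_standard
    rows.append(
        {
            "condition": profile.condition,
            "tag_name": "IS",
            "intensity": is_int,
            "quantity_pmol": np.nan,
            "is_standard": 1,
            "known_conc_pmol": is_conc,
        }
    )
    return pd.DataFrame(rows)


def profile_from_frame(frame: pd.DataFrame, condition: str | None = None) -> TagProfile:
    if condition is not None:
        frame = frame[frame["condition"] == condition]
    if frame.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    condition = str(frame["condition"].iloc[0])
    is_rows = frame[frame["is_standard"] == 1]
    if len(is_rows) != 1:
        raise ValueError("profile must contain exactly one internal-standard row")
    species = []
    for _, row in frame[frame["is_standard"] == 0].iterrows():
        s = parse_species_name(row["tag_name"])
        q = row.get("quantity_pmol")
        species.append(
            replace(
                s,
                intensity=float(row["intensity"]),
                quantity=None if pd.isna(q) else float(q),
            )
        )
    return TagProfile(
        condition=condition,
        species=tuple(species),
        internal_standard=(float(is_rows["intensity"].iloc[0]), float(is_rows["known_conc_pmol"].iloc[0])),
    )
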