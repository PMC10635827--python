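"""Synthetic datasets with recorded ground truth for every pipeline stage.

Four generators emulate the four input kinds of the steatosis pipeline:

* two-channel organoid images (DAPI-like nuclei + Nile-Red-like lipid
  droplets) with an exact ground-truth droplet mask and coverage;
* [U-13C]-glucose isotopologue tables with a known true DNL fraction;
* chain-resolved TAG species tables with an internal standard and known
  condition fold changes;
* drug-screen coverage tables with known per-dose true effects.

Every generator takes an explicit seed (no global random state), is
bit-reproducible given (scenario, seed), and attaches a ``GroundTruth``
record so downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from skimage import draw

from .lipidomics import TagProfile, parse_species_name
from .tracing import IsotopologueTable

__all__ = [
    "GroundTruth",
    "ImageScenario",
    "AnnotatedImage",
    "make_organoid_image",
    "FattyAcid",
    "LabelingScenario",
    "make_isotopologue_dataset",
    "TagScenario",
    "make_tag_profile",
    "default_intracellular_tag_scenario",
    "default_secretion_tag_scenario",
    "DrugSpec",
    "ScreenScenario",
    "make_screen_dataset",
]

IMAGE_DTYPE = np.uint16
_AMPLITUDE = 30000.0  # signal amplitude in 16-bit counts
_BACKGROUND = 1500.0


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters attached to a synthetic dataset."""

    values: dict[str, Any]

    def __getitem__(self, key: str):
        return self.values[key]


# --------------------------------------------------------------------------
# Organoid images
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageScenario:
    """Parameters of one synthetic two-channel organoid image.

    The defaults emulate a single confocal field of a steatotic organoid
    (vehicle-treated VLDL-secretion-defective line, ~30% droplet
    coverage) imaged at a scale where the organoid spans most of a
    512 x 512 frame.  ``n_droplets`` is a placement budget: droplets are
    added until the target coverage is reached, and the generator raises
    if the budget or the radii make the target unreachable.
    """

    image_size_px: tuple[int, int] = (512, 512)
    organoid_radius_px: int = 180
    n_droplets: int = 400
    droplet_radius_px_range: tuple[int, int] = (3, 12)
    target_coverage_fraction: float = 0.30
    nucleus_count: int = 400
    nucleus_radius_px_range: tuple[int, int] = (5, 8)
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.target_coverage_fraction <= 1.0:
            raise ValueError("target_coverage_fraction must lie in [0, 1]")
        r_min, r_max = self.droplet_radius_px_range
        if r_min <= 0 or r_max < r_min:
            raise ValueError("droplet radii must be positive with min <= max")
        if self.organoid_radius_px <= 0:
            raise ValueError("organoid radius must be positive")
        if self.organoid_radius_px * 2 >= min(self.image_size_px):
            raise ValueError("organoid does not fit inside the image")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        # upper bound on reachable coverage: every droplet at max radius,
        # no overlap
        reachable = self.n_droplets * math.pi * r_max**2 / (math.pi * self.organoid_radius_px**2)
        if self.target_coverage_fraction > min(1.0, reachable):
            raise ValueError(
                "infeasible coverage: n_droplets x max droplet area cannot "
                f"reach target {self.target_coverage_fraction} "
                f"(upper bound {reachable:.3f})"
            )


@dataclass(frozen=True)
class AnnotatedImage:
    """Synthetic image pair plus ground-truth masks and coverage."""

    nuclei: np.ndarray
    lipid: np.ndarray
    organoid_mask: np.ndarray
    droplet_mask: np.ndarray
    coverage: float  # droplet pixels / organoid pixels, exact
    truth: GroundTruth


def _disk_coords(center, radius, shape):
    return draw.disk(center, radius, shape=shape)


def make_organoid_image(scenario: ImageScenario) -> AnnotatedImage:
    """Render a two-channel organoid image with known droplet coverage.

    Nuclei and droplets are bright disks placed uniformly inside the
    organoid disk (droplets fully inside); droplet disks are added until
    the union mask reaches the target coverage, shrinking the sampled
    radius near the target so the recorded coverage lands within ~1% of
    it.  Additive Gaussian noise at ``noise_sd`` (fraction of the signal
    amplitude) is applied to both channels; output is 16-bit unsigned.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    shape = tuple(scenario.image_size_px)
    center = (shape[0] / 2.0, shape[1] / 2.0)
    r_org = scenario.organoid_radius_px

    organoid = np.zeros(shape, dtype=bool)
    organoid[_disk_coords(center, r_org, shape)] = True
    roi_px = int(organoid.sum())

    def random_center(max_offset: float) -> tuple[float, float]:
        # uniform over the disk of radius max_offset around the organoid center
        u = rng.uniform()
        theta = rng.uniform(0.0, 2.0 * math.pi)
        rad = max_offset * math.sqrt(u)
        return (center[0] + rad * math.sin(theta), center[1] + rad * math.cos(theta))

    nuclei_mask = np.zeros(shape, dtype=bool)
    n_min, n_max = scenario.nucleus_radius_px_range
    for _ in range(scenario.nucleus_count):
        r = int(rng.integers(n_min, n_max + 1))
        # nuclei centers fill the whole organoid disk: rim nuclei may bulge
        # slightly past the boundary, as they do in a real epithelium
        nuclei_mask[_disk_coords(random_center(r_org), r, shape)] = True

    droplet_mask = np.zeros(shape, dtype=bool)
    target_px = int(round(scenario.target_coverage_fraction * roi_px))
    r_min, r_max = scenario.droplet_radius_px_range
    placed = 0
    while droplet_mask.sum() < target_px and placed < scenario.n_droplets:
        remaining = target_px - int(droplet_mask.sum())
        r_cap = max(r_min, int(math.ceil(math.sqrt(remaining / math.pi))))
        r = min(int(rng.integers(r_min, r_max + 1)), r_cap)
        droplet_mask[_disk_coords(random_center(max(r_org - r, 0)), r, shape)] = True
        placed += 1

    coverage = float(droplet_mask.sum()) / roi_px
    if coverage < scenario.target_coverage_fraction - 0.01:
        raise ValueError(
            "infeasible coverage: droplet budget exhausted at coverage "
            f"{coverage:.3f} < target {scenario.target_coverage_fraction}"
        )

    def render(mask: np.ndarray, amplitude_frac: float) -> np.ndarray:
        img = np.full(shape, _BACKGROUND)
        img[mask] = _BACKGROUND + amplitude_frac * _AMPLITUDE
        if scenario.noise_sd > 0:
            img = img + rng.normal(0.0, scenario.noise_sd * _AMPLITUDE, size=shape)
        return np.clip(img, 0, np.iinfo(IMAGE_DTYPE).max).astype(IMAGE_DTYPE)

    truth = GroundTruth(
        {
            "coverage": coverage,
            "roi_area_px": roi_px,
            "droplet_area_px": int(droplet_mask.sum()),
            "n_droplets_placed": placed,
            "scenario": scenario,
        }
    )
    return AnnotatedImage(
        nuclei=render(nuclei_mask, 0.75),
        lipid=render(droplet_mask, 0.85),
        organoid_mask=organoid,
        droplet_mask=droplet_mask,
        coverage=coverage,
        truth=truth,
    )


# --------------------------------------------------------------------------
# Isotope labeling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FattyAcid:
    name: str
    n_carbons: int
    n_acetyl_units: int
    essential: bool
    abundance: float  # molar fraction of the pool


#: Default intracellular fatty-acid pool of a hepatocyte organoid: the five
#: most abundant nonessential species dominate (>90% of the pool), with
#: minor essential (C18:2, C20:4) and trace nonessential (C20:1) species.
DEFAULT_FATTY_ACIDS: tuple[FattyAcid, ...] = (
    FattyAcid("C14:0", 14, 7, False, 0.030),
    FattyAcid("C16:0", 16, 8, False, 0.295),
    FattyAcid("C16:1", 16, 8, False, 0.080),
    FattyAcid("C18:0", 18, 9, False, 0.100),
    FattyAcid("C18:1", 18, 9, False, 0.400),
    FattyAcid("C18:2", 18, 9, True, 0.055),
    FattyAcid("C20:4", 20, 10, True, 0.030),
    FattyAcid("C20:1", 20, 10, False, 0.010),
)


@dataclass(frozen=True)
class LabelingScenario:
    """[U-13C]-glucose labeling experiment parameters.

    Defaults reflect a VLDL-secretion-defective organoid culture in which
    glucose-driven DNL accrues linearly at 12% of the fatty-acid pool per
    day (~60% cumulative by day 5), with acetyl-CoA precursor enrichment
    0.8 (unlabeled acetyl-CoA from untraced pyruvate/glutamine/amino
    acids keeps it below 1), natural 13C abundance 1.07%, 5% of
    pre-existing chains elongated by one acetyl unit, 5% multiplicative
    measurement noise and n = 2 replicate quantifications.
    """

    fatty_acids: tuple[FattyAcid, ...] = DEFAULT_FATTY_ACIDS
    true_dnl_fraction_per_day: float = 0.12
    days: int = 5
    precursor_enrichment: float = 0.8
    natural_13c_abundance: float = 0.0107
    elongation_fraction: float = 0.05
    noise_cv: float = 0.05
    n_replicates: int = 2
    seed: int = 0

    @property
    def cumulative_fraction(self) -> float:
        return self.true_dnl_fraction_per_day * self.days

    def validate(self) -> None:
        for p, name in (
            (self.precursor_enrichment, "precursor_enrichment"),
            (self.natural_13c_abundance, "natural_13c_abundance"),
            (self.elongation_fraction, "elongation_fraction"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.cumulative_fraction <= 1.0:
            raise ValueError("cumulative DNL fraction (per-day rate x days) must lie in [0, 1]")
        total = sum(fa.abundance for fa in self.fatty_acids)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"molar abundance fractions must sum to 1 (got {total})")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def _isotopologue_expectation(fa: FattyAcid, scenario: LabelingScenario) -> np.ndarray:
    """Noise-free isotopologue distribution of one fatty acid.

    Three molecule classes: unlabeled pre-existing, pre-existing
    elongated by one acetyl unit (shift +2 when the added unit is
    labeled, which happens at the precursor enrichment), and de novo
    molecules whose labeled-unit count is Binomial(n_acetyl_units,
    enrichment) with each 13C2 unit adding +2 Da.  Every class is then
    convolved with the natural-abundance shift distribution of the
    remaining carbons, truncated at n_carbons and renormalized.
    """
    n = fa.n_carbons
    f = 0.0 if fa.essential else scenario.cumulative_fraction
    e = scenario.precursor_enrichment
    eg = scenario.elongation_fraction

    comp = np.zeros(n + 1)
    comp[0] += (1.0 - f) * (1.0 - eg)          # pre-existing, not elongated
    comp[0] += (1.0 - f) * eg * (1.0 - e)      # elongated with unlabeled unit
    comp[2] += (1.0 - f) * eg * e              # elongated with 13C2 unit
    if f > 0:
        k = np.arange(fa.n_acetyl_units + 1)
        pk = stats.binom.pmf(k, fa.n_acetyl_units, e)
        np.add.at(comp, np.minimum(2 * k, n), f * pk)

    nat = stats.binom.pmf(np.arange(n + 1), n, scenario.natural_13c_abundance)
    vec = np.convolve(comp, nat)[: n + 1]
    return vec / vec.sum()


def make_isotopologue_dataset(
    scenario: LabelingScenario,
) -> tuple[IsotopologueTable, GroundTruth]:
    """Generate a replicate isotopologue table with known DNL truth."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    sigma = math.sqrt(math.log1p(scenario.noise_cv**2)) if scenario.noise_cv > 0 else 0.0
    rows = []
    for rep in range(1, scenario.n_replicates + 1):
        for fa in scenario.fatty_acids:
            vec = _isotopologue_expectation(fa, scenario)
            if sigma > 0:
                vec = vec * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=vec.size))
                vec = vec / vec.sum()
            for shift, inten in enumerate(vec):
                rows.append(
                    {
                        "fatty_acid": fa.name,
                        "n_carbons": fa.n_carbons,
                        "shift": shift,
                        "intensity": inten,
                        "replicate": rep,
                        "abundance": fa.abundance,
                    }
                )
    truth = GroundTruth(
        {
            "cumulative_dnl_fraction": scenario.cumulative_fraction,
            "per_fa_fraction": {
                fa.name: (0.0 if fa.essential else scenario.cumulative_fraction)
                for fa in scenario.fatty_acids
            },
            "scenario": scenario,
        }
    )
    return IsotopologueTable(pd.DataFrame(rows)), truth


# --------------------------------------------------------------------------
# TAG lipidomics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TagScenario:
    """Condition-resolved TAG profile generator.

    ``species`` maps chain-resolved TAG names to (mean quantity in pmol,
    lognormal CV).  ``condition_fold_changes`` scales the TOTAL TAG of a
    condition relative to the reference (fold 1); an optional per-species
    bias map reshapes the composition of a condition before the total is
    renormalized to the requested fold, which is how saturated-chain
    enrichment (FADS2 loss) or PUFA enrichment (FADS2 overexpression)
    are encoded without changing the total-TAG truth.
    """

    species: tuple[tuple[str, float, float], ...]  # (name, mean pmol, cv)
    condition_fold_changes: Mapping[str, float]
    condition_species_bias: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    internal_standard_concentration: float = 10.0  # pmol per sample
    internal_standard_intensity: float = 1.0e5
    seed: int = 0

    def validate(self) -> None:
        if any(mean <= 0 for _, mean, _ in self.species):
            raise ValueError("all species mean quantities must be positive")
        if any(cv < 0 for _, _, cv in self.species):
            raise ValueError("species CVs must be non-negative")
        if self.internal_standard_concentration <= 0 or self.internal_standard_intensity <= 0:
            raise ValueError("internal standard concentration and intensity must be positive")
        folds = dict(self.condition_fold_changes)
        if not any(abs(v - 1.0) < 1e-12 for v in folds.values()):
            raise ValueError("one condition must be the reference with fold change 1")
        if any(v <= 0 for v in folds.values()):
            raise ValueError("fold changes must be positive")


def make_tag_profile(scenario: TagScenario, condition: str) -> tuple[TagProfile, GroundTruth]:
    """Draw one TAG profile for ``condition`` with a spiked internal standard.

    Per-species quantities are mean-corrected lognormal draws around
    mean x fold (x bias, renormalized to preserve the total fold), and
    species intensities are emitted so that internal-standard
    quantification recovers the drawn quantities exactly.
    """
    scenario.validate()
    if condition not in scenario.condition_fold_changes:
        raise KeyError(f"unknown condition {condition!r}")
    # seed offset per condition keeps profiles independent but reproducible
    cond_index = sorted(scenario.condition_fold_changes).index(condition)
    rng = np.random.default_rng((scenario.seed, cond_index))

    fold = scenario.condition_fold_changes[condition]
    bias = dict(scenario.condition_species_bias.get(condition, {}))
    base_total = sum(mean for _, mean, _ in scenario.species)
    biased = [(name, mean * bias.get(name, 1.0), cv) for name, mean, cv in scenario.species]
    biased_total = sum(mean for _, mean, _ in biased)
    scale = fold * base_total / biased_total

    from dataclasses import replace

    species = []
    true_quantities = {}
    for name, mean, cv in biased:
        mu = mean * scale
        if cv > 0:
            sigma = math.sqrt(math.log1p(cv**2))
            q = mu * math.exp(rng.normal(-0.5 * sigma**2, sigma))
        else:
            q = mu
        true_quantities[name] = q
        skel = parse_species_name(name)
        intensity = q / scenario.internal_standard_concentration * scenario.internal_standard_intensity
        species.append(replace(skel, intensity=intensity))

    profile = TagProfile(
        condition=condition,
        species=tuple(species),
        internal_standard=(
            scenario.internal_standard_intensity,
            scenario.internal_standard_concentration,
        ),
    )
    truth = GroundTruth(
        {
            "condition": condition,
            "fold_change": fold,
            "total_tag_pmol": sum(true_quantities.values()),
            "expected_total_tag_pmol": fold * base_total,
            "quantities_pmol": true_quantities,
            "scenario": scenario,
        }
    )
    return profile, truth


#: Chain-resolved intracellular TAG composition of a steatotic hepatocyte
#: organoid.  C14:0/C16:0/C16:1/C18:0/C18:1 chains dominate the pool;
#: C18:2 and C20:4 chains are minor (dietary supply only in culture).
DEFAULT_TAG_SPECIES: tuple[tuple[str, float, float], ...] = (
    ("TAG 48:1 (14:0/16:0/18:1)", 6.0, 0.05),
    ("TAG 50:1 (16:0/16:0/18:1)", 14.0, 0.05),
    ("TAG 50:2 (16:0/16:1/18:1)", 11.0, 0.05),
    ("TAG 52:1 (16:0/18:0/18:1)", 8.0, 0.05),
    ("TAG 52:2 (16:0/18:1/18:1)", 16.0, 0.05),
    ("TAG 52:3 (16:0/18:1/18:2)", 7.0, 0.05),
    ("TAG 54:2 (18:0/18:1/18:1)", 6.0, 0.05),
    ("TAG 54:3 (18:1/18:1/18:1)", 8.0, 0.05),
    ("TAG 54:4 (18:1/18:1/18:2)", 3.0, 0.05),
    ("TAG 56:5 (16:0/18:1/22:4)", 1.5, 0.05),
    ("TAG 58:8 (18:2/20:4/20:2)", 1.0, 0.05),
)

_SATURATED_RICH = (
    "TAG 48:1 (14:0/16:0/18:1)",
    "TAG 50:1 (16:0/16:0/18:1)",
    "TAG 50:2 (16:0/16:1/18:1)",
    "TAG 52:1 (16:0/18:0/18:1)",
    "TAG 52:2 (16:0/18:1/18:1)",
    "TAG 54:2 (18:0/18:1/18:1)",
)
_PUFA_RICH = (
    "TAG 52:3 (16:0/18:1/18:2)",
    "TAG 54:4 (18:1/18:1/18:2)",
    "TAG 56:5 (16:0/18:1/22:4)",
    "TAG 58:8 (18:2/20:4/20:2)",
)


def default_intracellular_tag_scenario(seed: int = 0) -> TagScenario:
    """FADS2 perturbation scenario on a VLDL-secretion-defective steatotic baseline.

    Relative to the FADS2_WT reference, FADS2 knockout triples the total
    TAG (+200%) and shifts composition toward species carrying at least
    one fully saturated chain; FADS2 overexpression reduces total TAG to
    0.45-fold (>50% reduction) and enriches PUFA-containing, longer
    species.  The composition biases make the DNL index (C16:0/C18:2)
    rise under knockout and fall under overexpression.
    """
    ko_bias = {name: 2.5 for name in _SATURATED_RICH}
    ko_bias.update({name: 0.5 for name in _PUFA_RICH})
    oe_bias = {name: 0.35 for name in _SATURATED_RICH}
    oe_bias.update({name: 3.0 for name in _PUFA_RICH})
    return TagScenario(
        species=DEFAULT_TAG_SPECIES,
        condition_fold_changes={"FADS2_WT": 1.0, "FADS2_KO": 3.0, "FADS2_OE": 0.45},
        condition_species_bias={"FADS2_KO": ko_bias, "FADS2_OE": oe_bias},
        seed=seed,
    )


def default_secretion_tag_scenario(seed: int = 0) -> TagScenario:
    """VLDL-secretion scenario: WT culture supernatant vs blank medium.

    WT organoids actively secrete VLDL, enriching medium TAG ~25-fold
    over the trace amounts present in blank medium.
    """
    return TagScenario(
        species=DEFAULT_TAG_SPECIES,
        condition_fold_changes={"blank_medium": 1.0, "WT_supernatant": 25.0},
        seed=seed,
    )


# --------------------------------------------------------------------------
# Drug screens
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugSpec:
    """True per-dose effect of one drug (fraction of the steatotic excess
    removed; 0 = no effect, 1 = full reversion to WT) plus a per-dose
    toxicity mask."""

    name: str
    effects: tuple[float, float, float, float]
    toxic: tuple[bool, bool, bool, bool] = (False, False, False, False)


#: A screen panel emulating a candidate-drug study: direct and indirect DNL
#: inhibitors are effective at high dose, agonists of other pathways are
#: not, and a few top doses are cytotoxic.
DEFAULT_DRUGS: tuple[DrugSpec, ...] = (
    DrugSpec("ACC_i", (0.30, 0.60, 0.85, 0.97)),
    DrugSpec("DGAT2_i", (0.35, 0.65, 0.82, 0.92)),
    DrugSpec("FAS_i", (0.25, 0.50, 0.75, 0.88), (False, False, False, True)),
    DrugSpec("FXR_a", (0.10, 0.25, 0.40, 0.52)),
    DrugSpec("hFGF19", (0.12, 0.28, 0.42, 0.48)),
    DrugSpec("DGAT1_i", (0.02, 0.05, 0.10, 0.15)),
    DrugSpec("ACL_i", (0.00, 0.02, 0.04, 0.06)),
    DrugSpec("SCD1_i", (0.01, 0.03, 0.05, 0.08)),
    DrugSpec("hFGF21", (0.00, 0.01, 0.02, 0.03)),
    DrugSpec("PPARa_a", (0.00, 0.00, 0.01, 0.02), (False, False, False, True)),
    DrugSpec("THRb_a", (0.00, 0.01, 0.03, 0.05)),
    DrugSpec("SIRT1_a", (0.00, 0.00, 0.01, 0.02)),
)


@dataclass(frozen=True)
class ScreenScenario:
    """Drug-screen generator parameters.

    Coverage of a treated well regresses from the steatotic mean toward
    the WT mean in proportion to the drug's true effect; the defaults
    use the spontaneous steatosis levels of the genetic model (~30%
    coverage) against the WT baseline (~2%), with n = 3 organoid
    cultures per drug concentration.
    """

    drugs: tuple[DrugSpec, ...] = DEFAULT_DRUGS
    wt_coverage_mean: float = 0.02
    steatotic_coverage_mean: float = 0.30
    replicate_sd: float = 0.015
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.steatotic_coverage_mean <= self.wt_coverage_mean:
            raise ValueError("steatotic coverage mean must exceed WT coverage mean")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")


def make_screen_dataset(scenario: ScreenScenario) -> tuple[pd.DataFrame, GroundTruth]:
    """Per drug x dose x replicate coverage table with known effects.

    Toxic cells are flagged and carry no coverage value (NaN).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    span = scenario.steatotic_coverage_mean - scenario.wt_coverage_mean
    rows = []
    for drug in scenario.drugs:
        for dose_index, (effect, toxic) in enumerate(zip(drug.effects, drug.toxic)):
            for rep in range(1, scenario.n_replicates + 1):
                if toxic:
                    cov = np.nan
                else:
                    cov = (
                        scenario.steatotic_coverage_mean
                        - effect * span
                        + rng.normal(0.0, scenario.replicate_sd)
                    )
                rows.append(
                    {
                        "drug": drug.name,
                        "dose_index": dose_index,
                        "replicate": rep,
                        "coverage": cov,
                        "toxic": toxic,
                    }
                )
    best_effect = {
        d.name: max(
            (e for e, t in zip(d.effects, d.toxic) if not t), default=np.nan
        )
        for d in scenario.drugs
    }
    truth = GroundTruth(
        {
            "effects": {d.name: d.effects for d in scenario.drugs},
            "toxic": {d.name: d.toxic for d in scenario.drugs},
            "best_nontoxic_effect": best_effect,
            "true_order": sorted(
                (n for n, e in best_effect.items() if not np.isnan(e)),
                key=lambda n: (-best_effect[n], n),
            ),
            "scenario": scenario,
        }
    )
    return pd.DataFrame(rows), truth
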