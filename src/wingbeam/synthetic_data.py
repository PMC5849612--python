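"""Synthetic fixtures with analytic or planted ground truth.

Two families of generators make every stage of the pipeline testable
without fossil material:

* *section rasters* — discs, annuli and rotated elliptical rings whose
  cross-sectional properties have closed forms, optionally with planted
  vascular pores, so the geometry engine can be checked against exact
  answers;
* *trait datasets* — archosaur-like tables of 69 taxa across 12 locomotor
  categories on a time-calibrated tree, with volant categories' mean CA/TA
  below 0.60 and non-volant above, a J/M gradient running from flapping
  (low) to soaring (high) flight, body masses spanning five orders of
  magnitude, and Brownian-motion structured residuals simulated along the
  tree — the statistical structure the comparative analyses assume.

Every generator is reproducible bit-for-bit from its spec and seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .comparative_inference import TraitTable
from .phylo_model import Chronogram, simulate_bm
from .section_geometry import (
    ELLIPTICITY_FLAG_THRESHOLD,
    SectionMask,
    SectionProperties,
)

__all__ = [
    "SectionSpec",
    "SyntheticSection",
    "make_section",
    "CategorySpec",
    "DEFAULT_CATEGORIES",
    "DatasetSpec",
    "make_dataset",
    "make_mystery",
]


# ---------------------------------------------------------------------------
# Analytic section rasters


@dataclass(frozen=True)
class SectionSpec:
    """Parametric transverse section with closed-form properties.

    ``outer``/``inner`` are (major, minor) semi-axes in px; the major axis
    lies at ``rotation`` degrees (counterclockwise in the displayed image).
    A disc is an elliptical ring with equal semi-axes and no inner void.
    """

    outer: tuple[float, float]  # (major, minor) semi-axes, px
    inner: tuple[float, float] = (0.0, 0.0)
    rotation: float = 0.0  # degrees
    pixel_size: float = 1.0  # mm per px
    pore_count: int = 0
    pore_radius: float = 2.0  # px
    margin: int = 4  # empty border, px

    def __post_init__(self) -> None:
        a, b = self.outer
        ai, bi = self.inner
        if not (a > 0 and b > 0 and a >= b):
            raise ValueError("outer semi-axes must satisfy major >= minor > 0")
        if ai < 0 or bi < 0 or ai >= a or bi >= b:
            raise ValueError("inner void must lie strictly inside the outer ellipse")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    def analytic_truth(self) -> SectionProperties:
        """Closed-form section properties (continuous geometry), mm units."""
        a, b = self.outer
        ai, bi = self.inner
        px2 = self.pixel_size**2
        px4 = self.pixel_size**4
        ca = math.pi * (a * b - ai * bi) * px2
        ta = math.pi * a * b * px2
        # major axis along image rows at rotation 0: Ixx = ∫y² carries a³
        imax = math.pi * (b * a**3 - bi * ai**3) / 4.0 * px4
        imin = math.pi * (a * b**3 - ai * bi**3) / 4.0 * px4
        theta = 0.0
        if imax > imin:
            theta = ((self.rotation + 90.0) % 180.0) - 90.0
            if theta == -90.0:
                theta = 90.0
        ellipticity = imax / imin
        return SectionProperties(
            CA=ca,
            TA=ta,
            centroid=(0.0, 0.0),
            Ixx=imax,
            Iyy=imin,
            Ixy=0.0,
            Imax=imax,
            Imin=imin,
            theta=theta,
            J=imax + imin,
            ca_ta=ca / ta,
            ellipticity=ellipticity,
            ellipticity_flag=ellipticity > ELLIPTICITY_FLAG_THRESHOLD,
            specimen_id="synthetic",
        )


@dataclass(frozen=True)
class SyntheticSection:
    """A rasterised synthetic section plus its ground truth."""

    mask: SectionMask  # solid cortical profile (no pores)
    gray: np.ndarray  # uint8 grayscale with pores rendered dark
    truth: SectionProperties
    pore_count_planted: int
    pore_centers: tuple[tuple[float, float], ...]

    @property
    def n_true(self) -> int:
        return self.mask.n_true


_GREY_BONE = 220
_GREY_DARK = 20


def make_section(spec: SectionSpec, seed: int | None = None) -> SyntheticSection:
    """Rasterise a section spec (pixel-centre-in-shape test, no anti-aliasing).

    Pores, if requested, are disjoint circular voids planted fully interior
    to the cortex; they appear only in the grayscale image — the boolean
    cortical mask stays solid, mirroring the traced binary profiles the
    geometry stage consumes.
    """
    a, b = spec.outer
    ai, bi = spec.inner
    half = int(math.ceil(a)) + spec.margin
    size = 2 * half + 1
    # pixel-centre coordinates relative to the grid centre
    yy, xx = np.mgrid[0:size, 0:size]
    x = (xx + 0.5) - (half + 0.5)
    y = (yy + 0.5) - (half + 0.5)
    phi = math.radians(spec.rotation)
    c, s = math.cos(phi), math.sin(phi)
    # undo the planted rotation: minor axis along u, major along v
    u = c * x - s * y
    v = s * x + c * y
    outer_in = (u / b) ** 2 + (v / a) ** 2 <= 1.0
    if ai > 0 and bi > 0:
        inner_in = (u / bi) ** 2 + (v / ai) ** 2 < 1.0
    else:
        inner_in = np.zeros_like(outer_in)
    cortex = outer_in & ~inner_in

    gray = np.full((size, size), _GREY_DARK, dtype=np.uint8)
    gray[cortex] = _GREY_BONE

    centers: list[tuple[float, float]] = []
    if spec.pore_count > 0:
        rng = np.random.default_rng(seed)
        r = spec.pore_radius
        tries = 0
        while len(centers) < spec.pore_count:
            tries += 1
            if tries > 20_000:
                raise RuntimeError("could not place all pores; cortex too tight")
            cx = rng.uniform(-a, a)
            cy = rng.uniform(-a, a)
            # pore disk plus a 2-px clearance must stay inside the cortex
            du = c * cx - s * cy
            dv = s * cx + c * cy
            pad = r + 2.0
            if (du / (b - pad)) ** 2 + (dv / (a - pad)) ** 2 > 1.0:
                continue
            if ai > 0 and (du / (bi + pad)) ** 2 + (dv / (ai + pad)) ** 2 < 1.0:
                continue
            if any((cx - px0) ** 2 + (cy - py0) ** 2 < (2 * r + 2) ** 2 for px0, py0 in centers):
                continue
            centers.append((cx, cy))
        for cx, cy in centers:
            pore = (x - cx) ** 2 + (y - cy) ** 2 <= r * r
            gray[pore & cortex] = _GREY_DARK

    mask = SectionMask(
        pixels=cortex,
        pixel_size=spec.pixel_size,
        specimen_id="synthetic",
        section_label=f"ring a={a} b={b} rot={spec.rotation}",
    )
    return SyntheticSection(
        mask=mask,
        gray=gray,
        truth=spec.analytic_truth(),
        pore_count_planted=len(centers),
        pore_centers=tuple(centers),
    )


# ---------------------------------------------------------------------------
# Archosaur-like trait datasets


@dataclass(frozen=True)
class CategorySpec:
    """Generative parameters of one locomotor category."""

    close_label: str
    viscor_label: str
    n: int
    volant: bool
    ca_ta_h: float
    ca_ta_u: float
    log_jm_h: float  # log10 of J/M, mm⁴ g⁻¹
    log_jm_u: float
    mass_range: tuple[float, float]  # grams, log-uniform


#: Default study conditions: 69 taxa across 12 locomotor categories, volant
#: mean CA/TA below 0.60 and non-volant above, J/M rising from flapping to
#: soaring flight, masses 10 g – 10⁶ g.
DEFAULT_CATEGORIES: tuple[CategorySpec, ...] = (
    CategorySpec("burst", "short_flight", 8, True, 0.50, 0.48, 0.10, 0.05, (150, 1500)),
    CategorySpec("intermittent_bounding", "forward_flapping_bounding", 8, True,
                 0.42, 0.40, 0.18, 0.14, (10, 60)),
    CategorySpec("continuous_flapping", "high_frequency_flapping", 10, True,
                 0.46, 0.44, 0.38, 0.33, (100, 2000)),
    CategorySpec("flap_gliding", "undulating", 8, True, 0.42, 0.41, 0.55, 0.50, (50, 500)),
    CategorySpec("soaring", "gliding_soaring", 8, True, 0.40, 0.40, 0.80, 0.75, (1000, 10_000)),
    CategorySpec("volant_wing_propelled_diving", "volant_wing_propelled_diving", 5, True,
                 0.56, 0.55, 0.25, 0.20, (500, 5000)),
    CategorySpec("long_tailed_pterosaurian", "long_tailed_pterosaurian", 1, True,
                 0.55, 0.53, 0.30, 0.26, (90, 300)),
    CategorySpec("short_tailed_pterosaurian", "short_tailed_pterosaurian", 1, True,
                 0.34, 0.33, 0.85, 0.80, (3000, 7000)),
    CategorySpec("non_volant_wing_propelled_diving", "non_volant_wing_propelled_diving",
                 4, False, 0.78, 0.76, -0.40, -0.45, (1000, 5000)),
    CategorySpec("ratite_bipedal", "ratite_bipedal", 4, False,
                 0.72, 0.74, -0.55, -0.60, (10_000, 100_000)),
    CategorySpec("dinosaurian_bipedal", "dinosaurian_bipedal", 6, False,
                 0.75, 0.77, -0.50, -0.55, (1000, 1_000_000)),
    CategorySpec("dinosaurian_omnipedal", "dinosaurian_omnipedal", 3, False,
                 0.82, 0.84, -0.65, -0.70, (10_000, 1_000_000)),
    CategorySpec("crocodilian_quadrupedal", "crocodilian_quadrupedal", 3, False,
                 0.88, 0.90, -0.75, -0.80, (10_000, 100_000)),
)


@dataclass(frozen=True)
class DatasetSpec:
    """Generative spec of a full archosaur-like comparative dataset."""

    categories: tuple[CategorySpec, ...] = DEFAULT_CATEGORIES
    tree_shape: str = "birth-death"  # "birth-death" | "balanced" | "star"
    depth_my: float = 250.0
    bm_rate_ca: float = 6.4e-7  # per-MY variance of CA/TA deviations
    bm_rate_log_jm: float = 2.56e-6  # per-MY variance of log10 J/M deviations
    noise_sd_ca: float = 0.012
    noise_sd_log_jm: float = 0.04
    seed: int = 0

    @property
    def n_taxa(self) -> int:
        return sum(c.n for c in self.categories)


def _make_tree(spec: DatasetSpec, n: int, seed: int) -> Chronogram:
    if spec.tree_shape == "star":
        newick = "(" + ",".join(f"T{i}:{spec.depth_my}" for i in range(n)) + ");"
        tree = dendropy.Tree.get(data=newick, schema="newick")
    elif spec.tree_shape == "balanced":
        labels = [f"T{i}" for i in range(n)]

        def build(lo: int, hi: int, depth: float) -> str:
            if hi - lo == 1:
                return f"{labels[lo]}:{depth}"
            mid = (lo + hi + 1) // 2
            half = depth / 2.0
            return f"({build(lo, mid, half)},{build(mid, hi, half)}):{half}"

        tree = dendropy.Tree.get(data=build(0, n, spec.depth_my) + ";", schema="newick")
    elif spec.tree_shape == "birth-death":
        from dendropy.model import birthdeath

        tree = birthdeath.birth_death_tree(
            birth_rate=0.05,
            death_rate=0.0,
            num_extant_tips=n,
            rng=random.Random(seed),
        )
        # the process stops exactly at the n-th speciation, leaving the last
        # sister pair with zero-length tips; let every lineage run on a bit
        depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
        extra = 0.05 * depth
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = (leaf.edge.length or 0.0) + extra
        depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
        scale = spec.depth_my / depth
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    else:
        raise ValueError(f"unknown tree shape {spec.tree_shape!r}")
    tree.is_rooted = True
    return Chronogram(tree)


def make_dataset(
    spec: DatasetSpec, seed: int | None = None
) -> tuple[TraitTable, Chronogram, dict]:
    """Generate a trait table + chronogram with known plantings.

    Tips are renamed so that locomotor categories form contiguous blocks in
    the tree's leaf order (phylogenetically clustered categories, as in a
    real comparative sample). Each biomechanical trait is its category mean
    plus a Brownian-motion deviation simulated along the tree plus i.i.d.
    measurement noise; masses are log-uniform within each category's range.
    """
    if seed is None:
        seed = spec.seed
    n = spec.n_taxa
    rng = np.random.default_rng(seed)
    tree = _make_tree(spec, n, seed)

    # contiguous category blocks in leaf order
    leaf_labels = [leaf.taxon.label for leaf in tree.tree.leaf_node_iter()]
    new_names: list[str] = []
    category_of: dict[str, CategorySpec] = {}
    i = 0
    for cat in spec.categories:
        for j in range(cat.n):
            name = f"{cat.close_label}_{j + 1}"
            new_names.append(name)
            category_of[name] = cat
            i += 1
    rename = dict(zip(leaf_labels, new_names))
    for leaf in tree.tree.leaf_node_iter():
        leaf.taxon.label = rename[leaf.taxon.label]
    tree = Chronogram(tree.tree)
    tips = tree.tip_labels

    trait_defs = {
        "ca_ta_h": ("ca_ta_h", spec.bm_rate_ca, spec.noise_sd_ca),
        "ca_ta_u": ("ca_ta_u", spec.bm_rate_ca, spec.noise_sd_ca),
        "jm_h": ("log_jm_h", spec.bm_rate_log_jm, spec.noise_sd_log_jm),
        "jm_u": ("log_jm_u", spec.bm_rate_log_jm, spec.noise_sd_log_jm),
    }
    data: dict[str, list] = {c: [] for c in trait_defs}
    bm_dev = {
        col: simulate_bm(
            tree, sigma2, n_sims=1, seed=int(rng.integers(2**31))
        ).iloc[0]
        for col, (_, sigma2, _) in trait_defs.items()
    }
    rows = []
    for t in tips:
        cat = category_of[t]
        row: dict[str, object] = {}
        for col, (mean_attr, _, noise_sd) in trait_defs.items():
            mean = getattr(cat, mean_attr)
            value = mean + float(bm_dev[col][t]) + rng.normal(0.0, noise_sd)
            if col.startswith("jm"):
                value = 10.0**value  # planted on log10 scale
            else:
                value = float(np.clip(value, 0.05, 0.99))
            row[col] = value
        lo, hi = cat.mass_range
        row["mass_g"] = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
        row["volant"] = cat.volant
        row["scheme_viscor"] = cat.viscor_label
        row["scheme_close"] = cat.close_label
        row["is_mystery"] = False
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(tips, name="taxon"))
    truth = {
        "spec": spec,
        "seed": seed,
        "category_of": {t: category_of[t].close_label for t in tips},
        "bm_deviations": {c: bm_dev[c].to_dict() for c in bm_dev},
    }
    return TraitTable(df), tree, truth


def make_mystery(
    spec: DatasetSpec, category: str, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Draw unlabeled rows from one category's generative model.

    Stands in for fossil specimens of unknown locomotor habit: parameter
    values follow the category's mean plus i.i.d. noise, the locomotor
    labels are withheld, and the true category is recorded only in the
    ``truth_category`` column for test bookkeeping.
    """
    cats = {c.close_label: c for c in spec.categories}
    if category not in cats:
        raise KeyError(f"unknown category {category!r}")
    cat = cats[category]
    rng = np.random.default_rng(spec.seed + 7_919 if seed is None else seed)
    rows = []
    for i in range(n):
        row = {
            "ca_ta_h": float(cat.ca_ta_h + rng.normal(0, spec.noise_sd_ca)),
            "ca_ta_u": float(cat.ca_ta_u + rng.normal(0, spec.noise_sd_ca)),
            "jm_h": float(10 ** (cat.log_jm_h + rng.normal(0, spec.noise_sd_log_jm))),
            "jm_u": float(10 ** (cat.log_jm_u + rng.normal(0, spec.noise_sd_log_jm))),
            "mass_g": float(
                10 ** rng.uniform(np.log10(cat.mass_range[0]), np.log10(cat.mass_range[1]))
            ),
            "volant": None,
            "scheme_viscor": None,
            "scheme_close": None,
            "is_mystery": True,
            "truth_category": category,
        }
        rows.append(row)
    index = pd.Index([f"mystery_{category}_{i + 1}" for i in range(n)], name="taxon")
    return pd.DataFrame(rows, index=index)
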