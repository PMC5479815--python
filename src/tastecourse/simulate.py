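"""Synthetic two-replicate stage-series count data with known truth.

The generator emulates the statistical structure of a taste-organoid
growth series sampled at days 2, 4, 6, 8, 10, 12 and 14:

* four temporal archetypes — a steep late rise (taste-receptor-like genes),
  an early fast rise that slows late (signalling / differentiation genes),
  flat housekeeping profiles, and a drop between days 4 and 6 followed by a
  plateau (proliferation genes) — in roughly the proportions observed for
  the four K-means clusters of the study system (4.0 / 14.1 / 68.4 / 13.5%);
* negative-binomial count noise with gene-wise dispersion phi
  (variance = mu + phi * mu^2);
* two replicate series whose per-gene log2 baselines differ by a Gaussian
  offset, so profiles are correlated but not identical;
* a planted gene category ("taste transduction"-like) sampled preferentially
  from late-rise genes, plus random decoy categories, so enrichment ranking
  is testable end to end.

Counts are drawn with mean ``mu_gj = e_gj * length_g * total_j / 1e9`` where
``e_gj = base_mean * 2**(template_g[j] + replicate_offset_g)`` is the
expression level on the RPKM scale; by construction the expected RPKM of a
gene equals ``e_gj`` regardless of its length or the stage's library size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import StageMatrix
from .enrich import GeneSetCollection
from .errors import ConfigError

DAYS = (2, 4, 6, 8, 10, 12, 14)
STAGES = tuple(f"d{d}" for d in DAYS)

ARCHETYPE_NAMES = ("late_rise", "early_rise", "flat", "early_drop")

#: Default log2 templates over days 2..14.  The late rise spans 8-fold
#: (taste-receptor-like genes go from near-undetectable to high), the early
#: rise 4-fold, and the drop is ~2.8-fold, concentrated between days 4 and 6
#: and flat afterwards.
DEFAULT_TEMPLATES: dict[str, tuple[float, ...]] = {
    "late_rise": (0.0, 0.0, 0.0, 0.0, 2.7, 2.85, 3.0),
    "early_rise": (0.0, 0.4, 0.75, 1.15, 1.4, 1.7, 2.0),
    "flat": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "early_drop": (0.0, 0.0, -1.5, -1.5, -1.5, -1.5, -1.5),
}

#: Cluster-size proportions of the study system (559/1998/9658/1909 of 14124).
DEFAULT_FRACTIONS: dict[str, float] = {
    "late_rise": 0.040,
    "early_rise": 0.141,
    "flat": 0.684,
    "early_drop": 0.135,
}


def _check_shape(name: str, t: np.ndarray) -> None:
    inc = np.diff(t)
    if name == "late_rise":
        if (inc < -1e-12).any():
            raise ConfigError("late_rise template must be non-decreasing")
        if inc[3:].sum() <= inc[:3].sum():
            raise ConfigError("late_rise must rise mostly at days >= 10")
    elif name == "early_rise":
        if (inc < -1e-12).any():
            raise ConfigError("early_rise template must be non-decreasing")
        if inc[:3].sum() <= inc[3:].sum():
            raise ConfigError("early_rise must rise mostly before day 8")
    elif name == "flat":
        if not np.allclose(t, t[0]):
            raise ConfigError("flat template must be constant")
    elif name == "early_drop":
        if not t[2] < t[1]:
            raise ConfigError("early_drop must decrease between days 4 and 6")
        if not np.allclose(t[2:], t[2]):
            raise ConfigError("early_drop must be constant from day 6 onward")
    else:
        raise ConfigError(f"unknown archetype name {name!r}")


@dataclass(frozen=True)
class ArchetypeSpec:
    """One temporal archetype: name, log2 template over the 7 days, fraction."""

    name: str
    template: tuple[float, ...]
    fraction: float

    def __post_init__(self) -> None:
        t = np.asarray(self.template, dtype=float)
        if t.shape != (len(DAYS),):
            raise ConfigError(f"template must have {len(DAYS)} levels")
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError("archetype fraction must lie in [0, 1]")
        _check_shape(self.name, t)

    @property
    def template_array(self) -> np.ndarray:
        return np.asarray(self.template, dtype=float)


def default_archetypes() -> tuple[ArchetypeSpec, ...]:
    return tuple(
        ArchetypeSpec(name, DEFAULT_TEMPLATES[name], DEFAULT_FRACTIONS[name])
        for name in ARCHETYPE_NAMES
    )


@dataclass(frozen=True)
class PlantedCategory:
    """A gene category sampled preferentially from late-rise genes.

    ``fold`` is the sampling odds ratio of a late-rise gene relative to any
    other gene; large values concentrate the category in the late-rise
    archetype the way taste-transduction genes concentrate in the steeply
    late-rising cluster.
    """

    name: str = "taste_transduction_like"
    size: int = 40
    fold: float = 50.0

    def __post_init__(self) -> None:
        if self.size < 1 or self.fold <= 0:
            raise ConfigError("planted category needs size >= 1 and fold > 0")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulated two-replicate experiment."""

    n_genes: int = 2000
    archetypes: tuple[ArchetypeSpec, ...] = field(default_factory=default_archetypes)
    base_mean: float = 20.0
    dispersion: float = 0.05
    replicate_shift_sd: float = 0.1
    library_sizes: tuple[float, ...] = (1e7,) * len(DAYS)
    gene_length_range: tuple[int, int] = (500, 5000)
    planted_category: PlantedCategory | None = field(default_factory=PlantedCategory)
    n_decoy_categories: int = 20
    decoy_size_range: tuple[int, int] = (20, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < len(self.archetypes):
            raise ConfigError("n_genes must be >= number of archetypes")
        total = sum(a.fraction for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"archetype fractions sum to {total}, not 1")
        if self.base_mean <= 0:
            raise ConfigError("base_mean must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.replicate_shift_sd < 0:
            raise ConfigError("replicate_shift_sd must be >= 0")
        if len(self.library_sizes) != len(DAYS):
            raise ConfigError(f"need {len(DAYS)} library sizes")
        if any(s <= 0 for s in self.library_sizes):
            raise ConfigError("library sizes must be positive")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ConfigError("gene_length_range must satisfy 1 <= min <= max")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class TruthLabels:
    """Ground-truth archetype per gene plus planted-category membership."""

    archetype: pd.Series  # gene id -> archetype name
    categories: dict[str, frozenset]

    def genes_of(self, *names: str) -> set:
        return set(self.archetype.index[self.archetype.isin(names)])

    def to_tsv(self, path) -> None:
        df = self.archetype.rename("archetype").to_frame()
        for name, members in self.categories.items():
            df[name] = df.index.isin(members).astype(int)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def expected_means(config: SimConfig, offsets: np.ndarray,
                   lengths: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Expected counts mu_gj for one replicate given per-gene log2 offsets."""
    e = config.base_mean * 2.0 ** (templates + offsets[:, None])
    lib = np.asarray(config.library_sizes, dtype=float)
    return e * lengths[:, None] * lib[None, :] / 1e9


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_dataset(
    config: SimConfig,
) -> tuple[StageMatrix, StageMatrix, TruthLabels, GeneSetCollection]:
    """Simulate two replicate count matrices with known archetype labels.

    Returns replicate A, replicate B, the truth labels, and a gene-set
    collection holding the planted category plus decoys over the full gene
    universe.  Identical configs (including seed) reproduce identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    names = [a.name for a in config.archetypes]
    fractions = np.array([a.fraction for a in config.archetypes])
    labels = rng.choice(names, size=n, p=fractions / fractions.sum())
    template_by_name = {a.name: a.template_array for a in config.archetypes}
    templates = np.stack([template_by_name[lab] for lab in labels])

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    offsets = rng.normal(0.0, config.replicate_shift_sd, size=(2, n))

    matrices = []
    for r in range(2):
        mu = expected_means(config, offsets[r], lengths.astype(float), templates)
        counts = _draw_counts(rng, mu, config.dispersion)
        df = pd.DataFrame(counts, index=gene_ids, columns=list(STAGES), dtype=float)
        matrices.append(
            StageMatrix(
                values=df,
                lengths_bp=pd.Series(lengths, index=gene_ids, dtype=int),
                value_kind="counts",
                mapped_totals=pd.Series(config.library_sizes, index=list(STAGES),
                                        dtype=float),
            )
        )

    categories: dict[str, frozenset] = {}
    if config.planted_category is not None:
        pc = config.planted_category
        weights = np.where(labels == "late_rise", pc.fold, 1.0)
        members = rng.choice(gene_ids.to_numpy(), size=min(pc.size, n),
                             replace=False, p=weights / weights.sum())
        categories[pc.name] = frozenset(members)
    for i in range(config.n_decoy_categories):
        size = int(rng.integers(config.decoy_size_range[0],
                                config.decoy_size_range[1] + 1))
        members = rng.choice(gene_ids.to_numpy(), size=min(size, n), replace=False)
        categories[f"decoy_{i:03d}"] = frozenset(members)

    truth = TruthLabels(
        archetype=pd.Series(labels, index=gene_ids, name="archetype"),
        categories=dict(categories),
    )
    collection = GeneSetCollection(
        categories={k: set(v) for k, v in categories.items()},
        background=set(gene_ids),
    )
    return matrices[0], matrices[1], truth, collection


def write_dataset(config: SimConfig, outdir) -> dict[str, str]:
    """Simulate and persist a dataset as TSV/GMT/JSON files; return paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rep_a, rep_b, truth, collection = generate_dataset(config)
    paths = {
        "counts_A": str(outdir / "counts_A.tsv"),
        "counts_B": str(outdir / "counts_B.tsv"),
        "truth": str(outdir / "truth.tsv"),
        "categories": str(outdir / "categories.gmt"),
        "config": str(outdir / "sim_config.json"),
    }
    rep_a.to_tsv(paths["counts_A"])
    rep_b.to_tsv(paths["counts_B"])
    truth.to_tsv(paths["truth"])
    collection.to_gmt(paths["categories"])
    config.to_json(paths["config"])
    return paths
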