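"""Synthetic expression data with planted co-expression modules.

Each module is driven by a single shared latent factor: gene g in module m
measures a_g * z_m(s) plus independent Gaussian noise, where z_m is a
per-sample standard-normal factor and the loading a_g is drawn uniformly
from `loading_range`.  Background genes are unit-variance independent
noise.  Differential expression is an additive mean shift on case samples
for a randomly chosen fraction of genes.  The construction makes recovery
analytically predictable: the population correlation of two genes in the
same module is a_g a_h / sqrt((a_g^2 + sd^2)(a_h^2 + sd^2)) and exactly 0
across modules.

All randomness derives from one master seed; each stage (loadings,
factors, noise, DE gene choice) uses a child generator at a fixed offset,
so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ExpressionMatrix, SampleGroups

# fixed per-stage seed offsets from the master seed
_OFF_LOADINGS, _OFF_FACTORS, _OFF_NOISE, _OFF_DE = 1, 2, 3, 4
_SEED_MOD = 2**31 - 1


class SyntheticSpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Generator settings; defaults are the standard study conditions
    (4 modules x 12 genes, 40 background genes, 50+50 samples)."""

    n_background_genes: int = 40
    module_sizes: tuple[int, ...] = (12, 12, 12, 12)
    loading_range: tuple[float, float] = (0.6, 1.0)
    noise_sd: float = 0.5
    n_case: int = 50
    n_control: int = 50
    de_fraction: float = 0.1
    de_effect: float = 1.0  # additive shift on cases, log-units
    seed: int = 0
    gene_prefix: str = ""

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.module_sizes):
            raise SyntheticSpecError("module sizes must be >= 2")
        if self.n_case + self.n_control < 4:
            raise SyntheticSpecError("need at least 4 samples in total")
        if not self.module_sizes and self.n_background_genes == 0:
            raise SyntheticSpecError("no genes: empty modules and zero background")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise SyntheticSpecError("de_fraction must be in [0, 1]")
        lo, hi = self.loading_range
        if not 0 < lo <= hi:
            raise SyntheticSpecError("loading_range must be positive with low <= high")
        if self.noise_sd < 0:
            raise SyntheticSpecError("noise_sd must be nonnegative")

    @property
    def n_genes(self) -> int:
        return sum(self.module_sizes) + self.n_background_genes


@dataclass
class SyntheticTruth:
    """Planted structure: module index per gene (-1 = background), DE flags."""

    module_of: dict[str, int]
    is_de: dict[str, bool] = field(default_factory=dict)

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == module]

    def de_genes(self) -> list[str]:
        return [g for g, f in self.is_de.items() if f]


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((seed + offset) % _SEED_MOD)


def _gene_names(spec: SyntheticSpec, module_names: list[str] | None = None) -> tuple[list[str], dict[str, int]]:
    names: list[str] = []
    module_of: dict[str, int] = {}
    for m, size in enumerate(spec.module_sizes):
        base = module_names[m] if module_names else f"{spec.gene_prefix}M{m}"
        for i in range(size):
            g = f"{base}_G{i:03d}"
            names.append(g)
            module_of[g] = m
    for i in range(spec.n_background_genes):
        g = f"{spec.gene_prefix}BG_G{i:03d}"
        names.append(g)
        module_of[g] = -1
    if len(set(names)) != len(names):
        raise SyntheticSpecError("gene-id collision in generator naming")
    return names, module_of


def generate_expression(
    spec: SyntheticSpec,
    module_names: list[str] | None = None,
) -> tuple[ExpressionMatrix, SampleGroups, SyntheticTruth]:
    """Draw one genes x samples dataset from the planted-module model."""
    names, module_of = _gene_names(spec, module_names)
    n_genes = len(names)
    n_samples = spec.n_case + spec.n_control
    sample_ids = [f"case_{i:03d}" for i in range(spec.n_case)] + [
        f"ctrl_{i:03d}" for i in range(spec.n_control)]
    case_mask = np.array([1.0] * spec.n_case + [0.0] * spec.n_control)

    loadings = _rng(spec.seed, _OFF_LOADINGS).uniform(*spec.loading_range, size=n_genes)
    factors = _rng(spec.seed, _OFF_FACTORS).standard_normal((len(spec.module_sizes), n_samples))
    noise_rng = _rng(spec.seed, _OFF_NOISE)

    values = np.empty((n_genes, n_samples))
    for i, g in enumerate(names):
        m = module_of[g]
        if m >= 0:
            values[i] = loadings[i] * factors[m] + noise_rng.standard_normal(n_samples) * spec.noise_sd
        else:
            values[i] = noise_rng.standard_normal(n_samples)

    n_de = round(spec.de_fraction * n_genes)
    de_idx = _rng(spec.seed, _OFF_DE).choice(n_genes, size=n_de, replace=False)
    is_de = {g: False for g in names}
    for i in de_idx:
        is_de[names[i]] = True
        values[i] += spec.de_effect * case_mask

    matrix = ExpressionMatrix(names, sample_ids, values)
    groups = SampleGroups({s: ("case" if s.startswith("case") else "control") for s in sample_ids})
    return matrix, groups, SyntheticTruth(module_of=module_of, is_de=is_de)


def generate_disease_pair(
    spec_a: SyntheticSpec,
    spec_b: SyntheticSpec,
    shared_modules: int,
):
    """Two datasets whose first `shared_modules` modules share gene memberships.

    Shared modules reuse identical gene ids in both datasets; all other
    module genes and background genes live in disjoint per-disease pools.
    Returns ((matrix_a, groups_a, truth_a), (matrix_b, groups_b, truth_b)).
    """
    if shared_modules > min(len(spec_a.module_sizes), len(spec_b.module_sizes)):
        raise SyntheticSpecError("shared_modules exceeds a disease's module count")
    for m in range(shared_modules):
        if spec_a.module_sizes[m] != spec_b.module_sizes[m]:
            raise SyntheticSpecError(f"shared module {m} has differing sizes")
    prefix_a = spec_a.gene_prefix or "A"
    prefix_b = spec_b.gene_prefix or "B"
    if prefix_a == prefix_b:
        raise SyntheticSpecError("disease gene prefixes must differ to keep pools disjoint")
    names_a = [f"SHARED_M{m}" if m < shared_modules else f"{prefix_a}_M{m}"
               for m in range(len(spec_a.module_sizes))]
    names_b = [f"SHARED_M{m}" if m < shared_modules else f"{prefix_b}_M{m}"
               for m in range(len(spec_b.module_sizes))]
    import dataclasses
    spec_a = dataclasses.replace(spec_a, gene_prefix=prefix_a + "_")
    spec_b = dataclasses.replace(spec_b, gene_prefix=prefix_b + "_")
    out_a = generate_expression(spec_a, module_names=names_a)
    out_b = generate_expression(spec_b, module_names=names_b)
    genes_a, genes_b = set(out_a[0].gene_ids), set(out_b[0].gene_ids)
    shared_expected = {g for g in genes_a if g.startswith("SHARED_")}
    overlap = genes_a & genes_b
    if overlap != shared_expected & genes_b:
        raise SyntheticSpecError("gene-id collision outside shared modules")
    return out_a, out_b
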