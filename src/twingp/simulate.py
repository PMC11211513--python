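"""Synthetic genotype/phenotype simulation.

Generates the data regime the twin regressor targets: biallelic SNP
dosages for many markers and few samples (n << m), with an additive
(optionally pairwise-epistatic) quantitative trait whose narrow-sense
heritability is controlled exactly on the realized sample.  Markers are
drawn under Hardy-Weinberg equilibrium without linkage disequilibrium;
see the methods note for what this does and does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import GenotypeMatrix, PhenotypeVector

__all__ = ["TraitSpec", "simulate_genotypes", "simulate_phenotypes",
           "make_fixture", "FIXTURES"]


@dataclass(frozen=True)
class TraitSpec:
    """Architecture of a simulated quantitative trait."""

    n_qtl: int = 10
    h2: float = 0.5
    architecture: str = "additive"
    effect_distribution: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be nonnegative")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must lie in [0, 1], got {self.h2}")
        if self.architecture not in ("additive",
                                     "additive_plus_pairwise_epistasis"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.effect_distribution not in ("gaussian", "laplace"):
            raise ValueError(
                f"unknown effect distribution {self.effect_distribution!r}")


def simulate_genotypes(n: int, m: int, maf_low: float = 0.05,
                       maf_high: float = 0.5, seed: int = 0,
                       ld_block: int = 0) -> GenotypeMatrix:
    """Dosage matrix with per-marker allele frequency ~ U[maf_low, maf_high].

    Dosages are Binomial(2, p_j), i.i.d. across samples (Hardy-Weinberg,
    no LD).  ``ld_block > 1`` switches on a crude block-correlation mode:
    markers within a block of that size share a latent gamete pair, for
    stress-testing kernel behaviour under correlated markers.
    """
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError(
            f"need 0 < maf_low <= maf_high <= 0.5, got [{maf_low}, {maf_high}]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=m)
    if ld_block and ld_block > 1:
        vals = np.empty((n, m), dtype=float)
        for start in range(0, m, ld_block):
            stop = min(start + ld_block, m)
            latent = rng.uniform(size=(n, 2))          # two gametes per sample
            for j in range(start, stop):
                # markers in a block threshold the same latent gametes
                vals[:, j] = (latent[:, 0] < p[j]).astype(float) \
                    + (latent[:, 1] < p[j]).astype(float)
    else:
        vals = rng.binomial(2, p, size=(n, m)).astype(float)
    return GenotypeMatrix(vals)


def simulate_phenotypes(G: GenotypeMatrix, spec: TraitSpec):
    """Simulate a trait on genotypes G with exact realized heritability.

    The genetic value is g = sum_j beta_j x_j over ``n_qtl`` sampled
    causal markers (plus products over random QTL pairs in the epistatic
    mode).  Environmental noise is residualized against g and rescaled
    so that Var(g)/Var(y) equals ``h2`` exactly on this sample.

    Returns
    -------
    (Y, qtl_indices, genetic_values)
        Y : PhenotypeVector; the truth arrays support recovery tests.
    """
    n, m = G.values.shape
    if spec.n_qtl > m:
        raise ValueError(f"n_qtl={spec.n_qtl} exceeds m={m}")
    if spec.h2 == 1.0 and spec.n_qtl == 0:
        raise ValueError("h2=1 requires at least one causal marker")
    rng = np.random.default_rng(spec.seed)
    qtl = np.sort(rng.choice(m, size=spec.n_qtl, replace=False))

    if spec.h2 == 0.0 or spec.n_qtl == 0:
        # pure-noise trait: no genetic signal is transmitted
        y = rng.standard_normal(n)
        Y = PhenotypeVector(y, list(G.sample_ids))
        return Y, qtl, np.zeros(n)

    if spec.effect_distribution == "gaussian":
        beta = rng.standard_normal(spec.n_qtl)
    else:
        beta = rng.laplace(size=spec.n_qtl)
    g = G.values[:, qtl] @ beta
    pairs = np.empty((0, 2), dtype=int)
    pair_beta = np.empty(0)
    if spec.architecture == "additive_plus_pairwise_epistasis" and spec.n_qtl >= 2:
        n_pairs = max(1, spec.n_qtl // 2)
        pairs = np.stack([rng.choice(spec.n_qtl, size=2, replace=False)
                          for _ in range(n_pairs)])
        if spec.effect_distribution == "gaussian":
            pair_beta = rng.standard_normal(n_pairs)
        else:
            pair_beta = rng.laplace(size=n_pairs)
        g = g + (G.values[:, qtl[pairs[:, 0]]]
                 * G.values[:, qtl[pairs[:, 1]]]) @ pair_beta

    var_g = float(np.var(g, ddof=1))
    if var_g == 0:
        raise ValueError(
            "realized genetic variance is zero (monomorphic causal markers); "
            "cannot reach the requested h2")
    if spec.h2 == 1.0:
        y = g.copy()
    else:
        e = rng.standard_normal(n)
        # make noise exactly orthogonal to g in-sample, then rescale so the
        # realized variance ratio hits h2
        gc = g - g.mean()
        e = e - e.mean()
        e = e - (e @ gc) / (gc @ gc) * gc
        e *= np.sqrt(var_g * (1.0 - spec.h2) / spec.h2 / np.var(e, ddof=1))
        y = g + e
    Y = PhenotypeVector(y, list(G.sample_ids))
    Y._truth_pairs = (pairs, pair_beta)  # used by make_fixture
    Y._truth_beta = beta
    return Y, qtl, g


# fixture name -> (n, m, maf range, genotype seed, TraitSpec)
FIXTURES = {
    "small_linear": (60, 30, (0.1, 0.5), 11,
                     TraitSpec(n_qtl=5, h2=0.8, seed=11)),
    "sparse_qtl": (50, 10, (0.2, 0.5), 5,
                   TraitSpec(n_qtl=1, h2=0.8, seed=5)),
    "kernel_nonlinear": (80, 20, (0.1, 0.5), 23,
                         TraitSpec(n_qtl=6, h2=0.9, seed=23,
                                   architecture="additive_plus_pairwise_epistasis")),
    "highdim_smalln": (100, 5000, (0.05, 0.5), 42,
                       TraitSpec(n_qtl=50, h2=0.6, seed=42)),
}


def make_fixture(name: str, out_dir):
    """Write a named fixture: genotype + phenotype tables and a truth file.

    Returns the dict of written paths.  The truth file records the causal
    marker indices, their effects and the target h2, so recovery tests
    can reconstruct the genetic values.
    """
    from .io import write_genotype_table, write_phenotype_table

    if name not in FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    n, m, (lo, hi), gseed, spec = FIXTURES[name]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    G = simulate_genotypes(n, m, lo, hi, seed=gseed)
    Y, qtl, g = simulate_phenotypes(G, spec)
    paths = {
        "genotypes": out_dir / f"{name}.genotypes.csv",
        "phenotypes": out_dir / f"{name}.phenotypes.csv",
        "truth": out_dir / f"{name}.truth.json",
    }
    write_genotype_table(G, paths["genotypes"])
    write_phenotype_table(Y, paths["phenotypes"])
    pairs, pair_beta = getattr(Y, "_truth_pairs", (np.empty((0, 2), int),
                                                  np.empty(0)))
    beta = getattr(Y, "_truth_beta", np.empty(0))
    truth = {
        "fixture": name,
        "n": n, "m": m,
        "h2": spec.h2,
        "n_qtl": spec.n_qtl,
        "architecture": spec.architecture,
        "genotype_seed": gseed,
        "trait_seed": spec.seed,
        "qtl_indices": [int(j) for j in qtl],
        "qtl_markers": [G.marker_ids[j] for j in qtl],
        "effects": [float(b) for b in beta],
        "epistatic_pairs": [[int(a), int(b)] for a, b in pairs],
        "epistatic_effects": [float(b) for b in pair_beta],
        "genetic_values": [float(v) for v in g],
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
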