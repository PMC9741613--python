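"""Gene-dropout simulator and synthetic reference / spatial dataset pairs.

The generator emulates the essential structure of a paired annotation
problem: a labeled dissociated reference and a spatial dataset drawn from
the *same* per-type expression profiles, with spatially coherent type
layouts (cortical-lamination-style bands or Gaussian blobs), negative-
binomial counts, and optional gene dropout.  A type can be withheld from
the reference while remaining present in the spatial data, creating the
ground truth for new-type discovery experiments.

Dropout is modelled as random gene discard: every matrix entry is
independently reset to zero with the given probability, emulating the
lower mRNA capture efficiency of spot-based platforms.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .datasets import ExpressionDataset

__all__ = ["simulate_dropout", "generate_synthetic_pair"]


def simulate_dropout(ds: ExpressionDataset, rate: float, seed: int = 0) -> ExpressionDataset:
    """Randomly reset matrix entries to zero with probability ``rate``.

    Acts uniformly on all entries (zeros stay zero); shape is preserved and
    the result is reproducible for a given seed.
    """
    if not 0 <= rate <= 1:
        raise ValueError("dropout rate must lie in [0, 1]")
    if ds.state != "raw":
        raise ValueError("dropout simulation expects raw counts")
    if rate == 0:
        return ds.with_counts(ds.counts.copy(), "raw")
    rng = np.random.default_rng(seed)
    mask = rng.random(ds.counts.shape) >= rate
    return ds.with_counts(ds.counts * mask, "raw")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts via the gamma–Poisson mixture.

    ``dispersion`` is the inverse size parameter: var = m + dispersion * m^2.
    """
    if dispersion <= 0:
        return rng.poisson(mean).astype(np.float64)
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam).astype(np.float64)


def generate_synthetic_pair(
    n_types: int = 10,
    n_genes: int = 100,
    n_ref_cells: int = 2000,
    n_srt_cells: int = 3000,
    separation: float = 1.0,
    spatial_layout: str = "bands",
    dropout_rate: float = 0.3,
    withhold_type: Optional[int] = None,
    dispersion: float = 0.3,
    boundary_mixing: float = 0.05,
    domain_um: float = 1000.0,
    seed: int = 0,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Generate a matched (reference, spatial) dataset pair.

    Per-type mean profiles are log-normal: gene baselines are drawn once,
    and each type modulates them by ``exp(separation * N(0,1))``, so
    ``separation`` directly scales between-type distance in log-expression
    space (1.0 is a moderately separable mixture; >= 3 is near-trivial).
    Reference counts are negative-binomial around the type profile.
    Spatial cells are laid out over a ``domain_um`` x ``domain_um`` field
    as horizontal bands (one per type, with ``boundary_mixing`` of cells
    swapped into a neighbouring band) or as Gaussian blobs; their counts
    come from the same profiles, then pass through the dropout simulator.

    ``withhold_type`` removes that type from the reference and its
    taxonomy while its cells remain in the spatial data, so discovery has a
    recoverable ground truth.  Everything is driven by a single seed.
    """
    if n_types < 2:
        raise ValueError("need at least 2 types")
    if withhold_type is not None and not (0 <= withhold_type < n_types):
        raise ValueError(f"withhold_type must be in [0, {n_types})")
    if spatial_layout not in ("bands", "blobs"):
        raise ValueError("spatial_layout must be 'bands' or 'blobs'")
    rng = np.random.default_rng(seed)
    type_names = [f"type_{i}" for i in range(n_types)]
    genes = [f"gene_{i:04d}" for i in range(n_genes)]

    # log-normal per-type mean profiles around shared gene baselines
    base = rng.normal(np.log(3.0), 0.8, size=n_genes)
    profiles = np.exp(base[None, :] + separation * rng.normal(size=(n_types, n_genes)))

    # ---- reference ----
    ref_types = list(range(n_types))
    if withhold_type is not None:
        ref_types.remove(withhold_type)
    ref_assign = np.asarray(ref_types)[rng.integers(0, len(ref_types), size=n_ref_cells)]
    ref_counts = _nb_sample(rng, profiles[ref_assign], dispersion)
    reference = ExpressionDataset(
        cells=[f"ref_{i}" for i in range(n_ref_cells)],
        genes=genes,
        counts=ref_counts,
        labels=[type_names[t] for t in ref_assign],
        taxonomy=[type_names[t] for t in ref_types],
    )

    # ---- spatial layout ----
    coords = rng.uniform(0.0, domain_um, size=(n_srt_cells, 2))
    if spatial_layout == "bands":
        band = np.floor(coords[:, 1] / (domain_um / n_types)).astype(int)
        band = np.clip(band, 0, n_types - 1)
        mix = rng.random(n_srt_cells) < boundary_mixing
        shift = rng.choice([-1, 1], size=n_srt_cells)
        band[mix] = np.clip(band[mix] + shift[mix], 0, n_types - 1)
        srt_assign = band
    else:
        centers = rng.uniform(0.1 * domain_um, 0.9 * domain_um, size=(n_types, 2))
        srt_assign = rng.integers(0, n_types, size=n_srt_cells)
        coords = centers[srt_assign] + rng.normal(0, 0.06 * domain_um, size=(n_srt_cells, 2))
    srt_counts = _nb_sample(rng, profiles[srt_assign], dispersion)
    srt = ExpressionDataset(
        cells=[f"srt_{i}" for i in range(n_srt_cells)],
        genes=genes,
        counts=srt_counts,
        coords=coords,
        labels=[type_names[t] for t in srt_assign],
        taxonomy=type_names,
    )
    if dropout_rate > 0:
        # child seed keeps the whole pair a function of the single input seed
        srt = simulate_dropout(srt, dropout_rate, seed=int(rng.integers(2 ** 31)))
    return reference, srt
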