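"""Per-droplet latent attributes of a multiplexed droplet experiment.

Each droplet gets a type (singlet / heterotypic doublet / empty), donor
identity(ies), a per-modality read depth, and an ambient read fraction — the
quantities a droplet-level generative model of a pooled snRNA/snATAC run
needs before any read is sampled.

Distributional choices where only summary levels are usually reported:

* ambient fraction ~ Beta(mu*c, (1-mu)*c): bounded support on [0,1] with the
  experiment-level ambient rate ``mu`` as mean and a concentration knob ``c``
  (default 30) controlling droplet-to-droplet spread;
* depth ~ NegativeBinomial(mean, dispersion): variance mean + mean^2/disp
  captures the overdispersion of per-droplet library sizes (dispersion ->
  infinity recovers Poisson);
* doublet native-read split ~ Beta(5, 5) for the first donor's share;
* empty droplets are ambient-only (ambient fraction exactly 1) with depth
  drawn at ``empty_depth_factor`` (default 5%) of the cell depth mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_reference import make_barcodes


@dataclass
class ExperimentConfig:
    """Experiment-level knobs. Defaults mirror a standard 10x-scale pooled
    multiome design: 9,000 droplets, 4 donors in equal proportion, 10%
    doublets, mean depths 25,000 (RNA) / 40,000 (ATAC) reads per droplet."""

    n_droplets: int = 9_000
    n_donors: int = 4
    doublet_rate: float = 0.10
    empty_rate: float = 0.0
    donor_proportions: list[float] | None = None
    ambient_level: float = 0.2          # experiment-level mean ambient fraction
    ambient_concentration: float = 30.0  # Beta concentration c
    rna_depth_mean: float = 25_000.0
    atac_depth_mean: float = 40_000.0
    depth_dispersion: float = 10.0
    doublet_mix_alpha: float = 5.0
    doublet_mix_beta: float = 5.0
    empty_depth_factor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.donor_proportions is None:
            self.donor_proportions = [1.0 / self.n_donors] * self.n_donors
        errors = []
        if self.n_droplets < 1:
            errors.append("n_droplets must be >= 1")
        if self.n_donors < 1:
            errors.append("n_donors must be >= 1")
        if not 0.0 <= self.doublet_rate <= 1.0:
            errors.append(f"doublet_rate {self.doublet_rate} outside [0, 1]")
        if not 0.0 <= self.empty_rate <= 1.0:
            errors.append(f"empty_rate {self.empty_rate} outside [0, 1]")
        if self.doublet_rate + self.empty_rate > 1.0:
            errors.append("doublet_rate + empty_rate exceeds 1")
        if len(self.donor_proportions) != self.n_donors:
            errors.append("donor_proportions length != n_donors")
        elif abs(sum(self.donor_proportions) - 1.0) > 1e-9:
            errors.append("donor_proportions must sum to 1")
        if not 0.0 <= self.ambient_level < 1.0:
            errors.append(f"ambient_level {self.ambient_level} outside [0, 1)")
        if self.ambient_concentration <= 0:
            errors.append("ambient_concentration must be positive")
        if self.rna_depth_mean <= 0 or self.atac_depth_mean <= 0:
            errors.append("depth means must be positive")
        if self.depth_dispersion <= 0:
            errors.append("depth_dispersion must be positive")
        if self.n_donors < 2 and self.doublet_rate > 0:
            errors.append("doublet_rate > 0 requires at least 2 donors")
        if errors:
            raise ValueError("invalid ExperimentConfig: " + "; ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DropletSpec:
    """Latent attributes of one droplet."""

    barcode: str
    droplet_type: str                 # "singlet" | "doublet" | "empty"
    donors: tuple[int, ...]           # 0, 1 or 2 donor indices
    doublet_mix: float                # donor-1 share of native reads (doublets)
    ambient_fraction: float
    rna_depth: int
    atac_depth: int


def sample_ambient_fraction(
    mu: float, concentration: float, rng: np.random.Generator, size: int | None = None
):
    """Beta(mu*c, (1-mu)*c) draw(s); mu = 0 yields exactly 0."""
    if not 0.0 <= mu < 1.0:
        raise ValueError("ambient mean must be in [0, 1)")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if mu == 0.0:
        return 0.0 if size is None else np.zeros(size)
    return rng.beta(mu * concentration, (1.0 - mu) * concentration, size=size)


def sample_depth(
    mean: float, dispersion: float, rng: np.random.Generator, size: int | None = None
):
    """Negative-binomial depth with variance mean + mean^2/dispersion."""
    if mean <= 0:
        raise ValueError("mean depth must be positive")
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def sample_droplets(
    cfg: ExperimentConfig, whitelist: list[str] | None = None
) -> list[DropletSpec]:
    """Draw ``cfg.n_droplets`` droplets i.i.d. from the experiment model.

    Types are multinomial over (singlet, doublet, empty); singlet donors
    follow ``donor_proportions``; doublets draw two *distinct* donors without
    replacement (heterotypic by construction). Deterministic under
    ``cfg.seed``. Barcodes come from ``whitelist`` (generated on the fly when
    omitted) without replacement.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_droplets
    if whitelist is None:
        whitelist = make_barcodes(n, seed=int(rng.integers(2**31)))
    if len(whitelist) < n:
        raise ValueError(f"whitelist has {len(whitelist)} barcodes for {n} droplets")
    barcodes = list(rng.choice(np.asarray(whitelist, dtype=object), size=n, replace=False))

    p_singlet = 1.0 - cfg.doublet_rate - cfg.empty_rate
    types = rng.choice(
        np.array(["singlet", "doublet", "empty"], dtype=object),
        size=n, p=[p_singlet, cfg.doublet_rate, cfg.empty_rate],
    )
    props = np.asarray(cfg.donor_proportions)
    rna_depth = sample_depth(cfg.rna_depth_mean, cfg.depth_dispersion, rng, size=n)
    atac_depth = sample_depth(cfg.atac_depth_mean, cfg.depth_dispersion, rng, size=n)
    empty_rna = sample_depth(
        max(cfg.rna_depth_mean * cfg.empty_depth_factor, 1.0),
        cfg.depth_dispersion, rng, size=n,
    )
    empty_atac = sample_depth(
        max(cfg.atac_depth_mean * cfg.empty_depth_factor, 1.0),
        cfg.depth_dispersion, rng, size=n,
    )
    ambient = np.asarray(
        sample_ambient_fraction(cfg.ambient_level, cfg.ambient_concentration, rng, size=n)
    )

    droplets: list[DropletSpec] = []
    for i in range(n):
        t = types[i]
        if t == "singlet":
            donors = (int(rng.choice(cfg.n_donors, p=props)),)
            mix = 1.0
            af = float(ambient[i])
            rd, ad = int(rna_depth[i]), int(atac_depth[i])
        elif t == "doublet":
            donors = tuple(
                int(d) for d in rng.choice(cfg.n_donors, size=2, replace=False, p=props)
            )
            mix = float(rng.beta(cfg.doublet_mix_alpha, cfg.doublet_mix_beta))
            af = float(ambient[i])
            rd, ad = int(rna_depth[i]), int(atac_depth[i])
        else:
            donors = ()
            mix = 0.0
            af = 1.0
            rd, ad = int(empty_rna[i]), int(empty_atac[i])
        droplets.append(
            DropletSpec(
                barcode=barcodes[i], droplet_type=str(t), donors=donors,
                doublet_mix=mix, ambient_fraction=af,
                rna_depth=rd, atac_depth=ad,
            )
        )
    return droplets


def droplets_to_frame(droplets: list[DropletSpec]) -> pd.DataFrame:
    """Tabular view: one row per droplet, donor indices as d1/d2 (-1 = none)."""
    return pd.DataFrame(
        {
            "barcode": [d.barcode for d in droplets],
            "droplet_type": [d.droplet_type for d in droplets],
            "donor_1": [d.donors[0] if d.donors else -1 for d in droplets],
            "donor_2": [d.donors[1] if len(d.donors) > 1 else -1 for d in droplets],
            "doublet_mix": [d.doublet_mix for d in droplets],
            "ambient_fraction": [d.ambient_fraction for d in droplets],
            "rna_depth": [d.rna_depth for d in droplets],
            "atac_depth": [d.atac_depth for d in droplets],
        }
    )


def write_truth(droplets: list[DropletSpec], path: str | Path) -> Path:
    path = Path(path)
    droplets_to_frame(droplets).to_csv(path, sep="\t", index=False)
    return path
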