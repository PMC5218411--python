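"""Configuration objects for the synthetic generator and the pipeline.

All generator laws (lognormal isochore lengths, Markov family succession,
Gaussian window-GC noise, Beta lamina contact frequencies, Poisson contacts
with power-law distance decay) are deliberate simplest-law choices that
reproduce the qualitative structures seen in real mammalian genomes; every
one of them is a knob here.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

FAMILIES = ("L1", "L2", "H1", "H2", "H3")

#: GC% targets per family, strictly increasing L1→H3; chosen to sit inside
#: the default fixed family ranges (cutpoints 37/41/46/53).
DEFAULT_GC_TARGETS = {"L1": 35.0, "L2": 39.0, "H1": 44.0, "H2": 49.5, "H3": 56.0}

#: (log-mean, log-sd) of lognormal isochore lengths in bp.  Medians fall in
#: the 0.2–2 Mb domain range; the GC-poorest (LAD-eligible) family is skewed
#: larger.
DEFAULT_LENGTH_PARAMS = {
    "L1": (math.log(1_200_000), 0.4),
    "L2": (math.log(900_000), 0.4),
    "H1": (math.log(750_000), 0.4),
    "H2": (math.log(600_000), 0.4),
    "H3": (math.log(500_000), 0.4),
}

# Family succession: zero diagonal (adjacent isochores have distinct
# families); mass decays with compositional distance so neighbours in GC are
# preferred successors, as in real isochore mosaics.
def _default_transition() -> np.ndarray:
    n = len(FAMILIES)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                mat[i, j] = 2.0 ** (-abs(i - j))
        mat[i] /= mat[i].sum()
    return mat


#: Beta(alpha, beta) parameters of nuclear-lamina contact frequencies per
#: LAD-eligible family.  L1 mean 0.8 (the "stable" high-CF contacts), L2
#: mean 0.5; L1 stochastically dominates L2.
DEFAULT_LAD_CF_PARAMS = {"L1": (8.0, 2.0), "L2": (4.0, 4.0)}

#: Planted CTCF site densities (sites per Mb), strictly increasing with GC.
DEFAULT_CTCF_DENSITIES = {"L1": 1.0, "L2": 3.0, "H1": 6.0, "H2": 10.0, "H3": 16.0}


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure genome generator."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 20_000_000
    family_gc_targets: dict = field(default_factory=lambda: dict(DEFAULT_GC_TARGETS))
    family_length_params: dict = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_PARAMS)
    )
    family_transition: np.ndarray = field(default_factory=_default_transition)
    #: lower truncation of drawn isochore lengths (bp).
    min_isochore_length: int = 200_000
    #: sd (GC%) of the Gaussian noise added to each noise_window tile.
    window_noise_sd: float = 1.0
    #: granularity at which window GC noise is applied.
    noise_window: int = 100_000
    #: sd (bp) of the Gaussian jitter applied to concordant TAD endpoints.
    tad_jitter_sd: float = 50_000.0
    #: fraction of TADs placed uniformly at random instead of on isochores.
    discordant_tad_fraction: float = 0.0
    lad_cf_params: dict = field(default_factory=lambda: dict(DEFAULT_LAD_CF_PARAMS))
    contact_resolution: int = 250_000
    decay_exponent: float = 1.0
    #: base expected contact count at one-bin separation.
    contact_base: float = 100.0
    #: multiplicative boost for bin pairs inside the same true isochore.
    domain_boost: float = 4.0
    #: multiplicative boost for GC-poor × GC-poor bin pairs at any distance;
    #: the long-range GC-poor signature emerges because GC-rich pairs decay
    #: without it.
    gcpoor_longrange_boost: float = 3.0
    #: planted fraction of inter-chromosomal interaction-hub bins that are
    #: GC-rich (the ~75%/25% class split).
    interchrom_gcrich_preference: float = 0.75
    #: interaction-hub bins per chromosome for the inter-chromosomal law.
    interchrom_hubs_per_chrom: int = 12
    #: Poisson intensity of hub×hub inter-chromosomal pairs / background.
    interchrom_hub_intensity: float = 60.0
    interchrom_background: float = 0.5
    ortholog_gc_noise_sd: float = 1.0
    genes_per_block: int = 5
    #: ortholog genes simulated per chromosome.
    orthologs_per_chrom: int = 250
    ctcf_densities: dict = field(default_factory=lambda: dict(DEFAULT_CTCF_DENSITIES))

    def __post_init__(self) -> None:
        self.family_transition = np.asarray(self.family_transition, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.chromosome_length <= 0 or self.contact_resolution <= 0:
            raise ValueError("lengths must be positive")
        if self.min_isochore_length <= 0:
            raise ValueError("min_isochore_length must be positive")
        if self.chromosome_length < self.min_isochore_length:
            raise ValueError(
                "chromosome_length smaller than one minimal isochore"
            )
        if self.noise_window <= 0:
            raise ValueError("noise_window must be positive")
        gc = [self.family_gc_targets[f] for f in FAMILIES]
        if not all(a < b for a, b in zip(gc, gc[1:])):
            raise ValueError("family_gc_targets must be strictly increasing L1→H3")
        t = self.family_transition
        if t.shape != (5, 5) or not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("family_transition must be 5x5 with rows summing to 1")
        if np.any(t < 0):
            raise ValueError("family_transition entries must be non-negative")
        for p in (self.discordant_tad_fraction, self.interchrom_gcrich_preference):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if self.genes_per_block < 3:
            raise ValueError(
                "genes_per_block < 3: blocks would be undetectable under the "
                "at-least-3-orthologs rule"
            )

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named stream under this config's seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream_key(stream),))
        )

    def stationary_families(self) -> np.ndarray:
        """Stationary distribution of the family succession chain."""
        t = self.family_transition
        vals, vecs = np.linalg.eig(t.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["family_transition"] = self.family_transition.tolist()
        return d


def stream_key(name: str) -> int:
    """Stable 32-bit key for a named random stream (CRC-32 of the name).

    Deriving stage seeds as ``SeedSequence(global_seed, spawn_key=(key,))``
    means adding a stage never perturbs any other stage's stream.
    """
    return zlib.crc32(name.encode("utf-8"))


@dataclass
class PipelineConfig:
    """End-to-end analysis configuration (embeds the generator config)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # isochore segmentation
    window: int = 100_000
    step: int = 0  # 0 → non-overlapping tiling (step = window)
    min_size: int = 200_000
    boundaries_mode: str = "fixed"
    # association
    n_perm: int = 199
    association_mode: str = "basepair"
    randomization: str = "uniform"
    max_shift: int = 2_500_000
    shift_step: int = 250_000
    sharpness_threshold: float = 2.0
    # synteny
    min_genes: int = 3
    # contacts
    distance_breaks: tuple = (1_000_000, 5_000_000, 20_000_000)
    top_n: int = 100
    boundary_tolerance: int = 100_000
    lad_cf_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step == 0:
            self.step = self.window
        if self.boundaries_mode not in ("fixed", "extended"):
            raise ValueError("boundaries_mode must be 'fixed' or 'extended'")
        if self.association_mode not in ("count", "basepair"):
            raise ValueError("association_mode must be 'count' or 'basepair'")
        if self.randomization not in ("uniform", "circular"):
            raise ValueError("randomization must be 'uniform' or 'circular'")
        if self.max_shift % self.shift_step != 0:
            raise ValueError("shift_step must divide max_shift")
        # the pipeline's global seed overrides the embedded generator seed
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        sim = SimulationConfig(**sim_raw)
        raw = {k: v for k, v in raw.items()}
        if "distance_breaks" in raw:
            raw["distance_breaks"] = tuple(raw["distance_breaks"])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["distance_breaks"] = list(self.distance_breaks)
        return d


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage seed below 2**31, derived from the global seed and stage name."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(stream_key(stage),))
    return int(ss.generate_state(1)[0] % (2**31))
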