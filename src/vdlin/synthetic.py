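"""Seeded synthetic compound libraries with a planted structure-activity rule.

Every compound is assembled from a small fragment vocabulary of valid SMILES
pieces; "active" compounds additionally carry a trifluoromethyl marker
fragment, and their replicate signatures receive the planted dual effect
(IFN panel genes up, inflammatory panel genes down). This gives downstream
stages a learnable structure -> signature task with known ground truth.

RNG recipe (documented so it can be reproduced independently):
  rng = np.random.default_rng(config.seed)
  1. is_planted_active = rng.random(n_compounds) < active_fraction
  2. per-compound child seeds = rng.integers(0, 2**63, size=n_compounds)
  3. compound i is generated entirely from default_rng(child_seeds[i])
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EmptyInputError
from .panel import DEFAULT_PANEL, GenePanel

# Fragment vocabulary: chemically valid, halogen/ring/chain variety, and
# guaranteed parseable by the built-in grammar. Every fragment stays valid
# under plain concatenation (halogens only inside branches); no fluorine
# outside the marker.
FRAGMENTS = (
    "CC",
    "CCO",
    "CN",
    "CCN",
    "CO",
    "CS",
    "C(Cl)C",
    "C(Br)C",
    "C(C)C",
    "CC(C)O",
    "c1ccccc1",
    "Cc1ccccc1",
    "CC=C",
)

# Trifluoromethyl branch, present iff the compound is a planted active.
ACTIVE_MARKER = "C(C(F)(F)F)"


@dataclass(frozen=True)
class SyntheticConfig:
    n_compounds: int = 1000
    replicate_count_range: tuple[int, int] = (1, 12)
    gene_universe_size: int = 50
    active_fraction: float = 0.3
    effect_size: float = 2.0
    noise_sd: float = 0.3
    seed: int = 0
    panel: GenePanel = field(default=DEFAULT_PANEL)

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ConfigurationError("n_compounds must be >= 1")
        lo, hi = self.replicate_count_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                "replicate_count_range must be an inclusive range with 1 <= lo <= hi"
            )
        if self.gene_universe_size < 10:
            raise ConfigurationError("gene_universe_size must be >= 10 (panel included)")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ConfigurationError("active_fraction must lie in [0, 1]")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class CompoundRecord:
    """One compound: id, structure, replicate signature matrix, ground truth."""

    compound_id: str
    smiles: str
    replicates: np.ndarray  # (n_replicates, n_genes)
    gene_names: tuple[str, ...]
    is_planted_active: bool = False

    def __post_init__(self) -> None:
        self.replicates = np.atleast_2d(np.asarray(self.replicates, dtype=float))
        if self.replicates.shape[0] < 1:
            raise ConfigurationError("a compound record needs >= 1 replicate")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ConfigurationError("gene column names must be unique")
        if self.replicates.shape[1] != len(self.gene_names):
            raise ConfigurationError("replicate matrix width must match gene names")

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[0]


def gene_universe(config: SyntheticConfig) -> tuple[str, ...]:
    """Panel genes plus filler genes, in a seeded shuffled column order."""
    fillers = [f"G{i:04d}" for i in range(config.gene_universe_size - 10)]
    names = list(config.panel.genes) + fillers
    order = np.random.default_rng(config.seed ^ 0x5EED).permutation(len(names))
    return tuple(names[i] for i in order)


def _assemble_smiles(rng: np.random.Generator, active: bool) -> str:
    n_frag = int(rng.integers(2, 6))
    parts = [FRAGMENTS[i] for i in rng.integers(0, len(FRAGMENTS), size=n_frag)]
    if active:
        parts.insert(int(rng.integers(0, n_frag + 1)), ACTIVE_MARKER)
    return "".join(parts)


def generate_library(config: SyntheticConfig) -> list[CompoundRecord]:
    """Generate ``config.n_compounds`` seeded compound records.

    Planted actives receive +effect_size on the IFN panel genes and
    -effect_size on the inflammatory panel genes in every replicate, plus
    zero-mean Gaussian noise everywhere; inactives receive noise only.
    """
    rng = np.random.default_rng(config.seed)
    is_active = rng.random(config.n_compounds) < config.active_fraction
    child_seeds = rng.integers(0, 2**63, size=config.n_compounds)

    genes = gene_universe(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    effect = np.zeros(len(genes))
    for g in config.panel.ifn_genes:
        effect[gene_index[g]] = config.effect_size
    for g in config.panel.inflammatory_genes:
        effect[gene_index[g]] = -config.effect_size

    lo, hi = config.replicate_count_range
    records: list[CompoundRecord] = []
    for i in range(config.n_compounds):
        crng = np.random.default_rng(child_seeds[i])
        n_rep = int(crng.integers(lo, hi + 1))
        deltas = crng.normal(0.0, config.noise_sd, size=(n_rep, len(genes)))
        if is_active[i]:
            deltas += effect
        records.append(
            CompoundRecord(
                compound_id=f"CPD{i:05d}",
                smiles=_assemble_smiles(crng, bool(is_active[i])),
                replicates=deltas,
                gene_names=genes,
                is_planted_active=bool(is_active[i]),
            )
        )
    return records


def split_library(
    library: list[CompoundRecord], train_fraction: float, seed: int
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Seeded uniform shuffle, then train size = floor(train_fraction * n).

    This convention reproduces a 5502/2359 partition of 7,861 compounds at
    train_fraction 0.7.
    """
    if not library:
        raise EmptyInputError("cannot split an empty library")
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must lie strictly in (0, 1)")
    order = np.random.default_rng(seed).permutation(len(library))
    n_train = math.floor(train_fraction * len(library))
    train = [library[i] for i in order[:n_train]]
    test = [library[i] for i in order[n_train:]]
    return train, test
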