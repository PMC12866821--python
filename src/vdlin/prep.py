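"""Signature preprocessing: replicate filtering, covariate-free averaging,
ternary labelling and panel selection."""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, EmptyInputError, SchemaError
from .panel import DEFAULT_PANEL, GenePanel, PanelProfile
from .synthetic import CompoundRecord

DEFAULT_MIN_REPLICATES = 7
DEFAULT_TAU = 0.5


def clean_library(
    records: list[CompoundRecord], min_replicates: int = DEFAULT_MIN_REPLICATES
) -> list[CompoundRecord]:
    """Drop compounds with fewer than ``min_replicates`` replicate signatures.

    Order is preserved; an empty result is allowed. Idempotent.
    """
    return [r for r in records if r.n_replicates >= min_replicates]


def average_profile(record: CompoundRecord) -> np.ndarray:
    """Arithmetic per-gene mean over all replicates, pooling every covariate
    (plate, dose, time, cell line are never distinguished)."""
    if record.replicates.shape[0] == 0:
        raise EmptyInputError(f"compound {record.compound_id!r} has no replicates")
    return record.replicates.mean(axis=0)


def ternarize(delta: np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Elementwise sign with a dead zone: +1 if delta > tau, -1 if delta < -tau,
    else 0 ("no significant change")."""
    if tau < 0:
        raise ConfigurationError("tau must be >= 0")
    delta = np.asarray(delta, dtype=float)
    return np.where(delta > tau, 1, np.where(delta < -tau, -1, 0)).astype(int)


def select_panel(
    mean_delta: np.ndarray,
    gene_names: tuple[str, ...] | list[str],
    panel: GenePanel = DEFAULT_PANEL,
    compound_id: str = "",
    tau: float = DEFAULT_TAU,
) -> PanelProfile:
    """Extract the 10 panel genes from a full-universe mean vector, reordered
    canonically (IFN block first). Gene matching is case-insensitive."""
    mean_delta = np.asarray(mean_delta, dtype=float)
    if mean_delta.shape != (len(gene_names),):
        raise SchemaError(
            f"mean_delta length {mean_delta.shape} does not match "
            f"{len(gene_names)} gene names"
        )
    lookup = {}
    for i, g in enumerate(gene_names):
        lookup.setdefault(g.upper(), i)
    values = np.empty(10)
    for j, gene in enumerate(panel.genes):
        idx = lookup.get(gene.upper())
        if idx is None:
            raise SchemaError(f"panel gene {gene} missing from the gene universe")
        values[j] = mean_delta[idx]
    return PanelProfile(
        compound_id=compound_id, delta=values, ternary=ternarize(values, tau)
    )


def prepare_profiles(
    records: list[CompoundRecord],
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    tau: float = DEFAULT_TAU,
    panel: GenePanel = DEFAULT_PANEL,
) -> list[PanelProfile]:
    """clean -> average -> select panel, for a whole library."""
    profiles = []
    for record in clean_library(records, min_replicates):
        mean = average_profile(record)
        profiles.append(
            select_panel(mean, record.gene_names, panel, record.compound_id, tau)
        )
    return profiles
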