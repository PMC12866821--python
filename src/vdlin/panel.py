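"""The 10-gene immune panel: five IFN-I/EGR1 genes whose upregulation is
rewarded and five NF-kB inflammatory genes whose downregulation is rewarded.

Canonical order is the IFN block (indices 0-4) followed by the inflammatory
block (indices 5-9). All panel math elsewhere assumes this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError

IFN_GENES = ("EGR1", "IFNB1", "ISG15", "IFIT3", "CXCL10")
INFLAMMATORY_GENES = ("IL1B", "IL6", "TNF", "PTGS2", "NOS2")


@dataclass(frozen=True)
class GenePanel:
    """Ordered 5+5 gene panel with the desired direction of regulation."""

    ifn_genes: tuple[str, ...] = IFN_GENES
    inflammatory_genes: tuple[str, ...] = INFLAMMATORY_GENES

    def __post_init__(self) -> None:
        if len(self.ifn_genes) != 5 or len(self.inflammatory_genes) != 5:
            raise SchemaError(
                "panel must have exactly 5 IFN genes and 5 inflammatory genes"
            )
        up = {g.upper() for g in self.ifn_genes}
        down = {g.upper() for g in self.inflammatory_genes}
        if up & down:
            raise SchemaError(f"panel gene(s) in both blocks: {sorted(up & down)}")

    @property
    def genes(self) -> tuple[str, ...]:
        """All 10 genes in canonical order (IFN block first)."""
        return self.ifn_genes + self.inflammatory_genes

    @property
    def directions(self) -> np.ndarray:
        """+1 for genes rewarded when up, -1 for genes rewarded when down."""
        return np.array([1] * len(self.ifn_genes) + [-1] * len(self.inflammatory_genes))

    def index_of(self, gene: str) -> int:
        """Case-insensitive lookup of a gene's canonical panel index."""
        target = gene.upper()
        for i, g in enumerate(self.genes):
            if g.upper() == target:
                return i
        raise SchemaError(f"gene {gene!r} is not in the panel")


DEFAULT_PANEL = GenePanel()


@dataclass
class PanelProfile:
    """Per-compound averaged panel signature plus its ternary labels."""

    compound_id: str
    delta: np.ndarray  # 10-vector, canonical panel order
    ternary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != (10,):
            raise SchemaError(
                f"panel profile for {self.compound_id!r} must be a 10-vector, "
                f"got shape {self.delta.shape}"
            )
        if self.ternary is not None:
            self.ternary = np.asarray(self.ternary, dtype=int)
            if self.ternary.shape != (10,):
                raise SchemaError("ternary labels must be a 10-vector")
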