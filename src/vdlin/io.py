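"""Plain-text readers/writers: .smi files, signature/profile/latents CSV,
JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .panel import DEFAULT_PANEL, GenePanel, PanelProfile
from .synthetic import CompoundRecord


def write_smi(records: list[CompoundRecord], path: str | Path) -> None:
    """One `SMILES<TAB>compound_id` line per compound."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles}\t{r.compound_id}\n")


def read_smi(path: str | Path) -> list[tuple[str, str]]:
    """Returns (smiles, compound_id) pairs; ids default to the line number."""
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            pairs.append((parts[0], parts[1] if len(parts) > 1 else f"MOL{i:05d}"))
    return pairs


def write_signatures(records: list[CompoundRecord], path: str | Path) -> None:
    """Long CSV: compound_id, replicate_id, then one column per gene."""
    frames = []
    for r in records:
        df = pd.DataFrame(r.replicates, columns=list(r.gene_names))
        df.insert(0, "replicate_id", [f"{r.compound_id}_r{j}" for j in range(r.n_replicates)])
        df.insert(0, "compound_id", r.compound_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_signatures(
    path: str | Path, smiles_map: dict[str, str] | None = None
) -> list[CompoundRecord]:
    """Inverse of :func:`write_signatures`; SMILES filled from ``smiles_map``
    when available (empty string otherwise)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"compound_id", "replicate_id"}
    if not required.issubset(df.columns):
        raise SchemaError(f"signatures file must contain columns {sorted(required)}")
    genes = tuple(c for c in df.columns if c not in required)
    smiles_map = smiles_map or {}
    records = []
    for cid, group in df.groupby("compound_id", sort=False):
        records.append(
            CompoundRecord(
                compound_id=str(cid),
                smiles=smiles_map.get(str(cid), ""),
                replicates=group[list(genes)].to_numpy(dtype=float),
                gene_names=genes,
            )
        )
    return records


def write_profiles(
    profiles: list[PanelProfile], path: str | Path, panel: GenePanel = DEFAULT_PANEL
) -> None:
    rows = {
        "compound_id": [p.compound_id for p in profiles],
    }
    for j, gene in enumerate(panel.genes):
        rows[gene] = [p.delta[j] for p in profiles]
    for j, gene in enumerate(panel.genes):
        rows[f"ternary_{gene}"] = [int(p.ternary[j]) for p in profiles]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles(
    path: str | Path, panel: GenePanel = DEFAULT_PANEL
) -> list[PanelProfile]:
    df = pd.read_csv(path)
    missing = [g for g in panel.genes if g not in df.columns]
    if missing:
        raise SchemaError(f"profiles file missing panel gene column(s): {missing}")
    profiles = []
    for _, row in df.iterrows():
        delta = np.array([row[g] for g in panel.genes], dtype=float)
        tern_cols = [f"ternary_{g}" for g in panel.genes]
        ternary = (
            np.array([row[c] for c in tern_cols], dtype=int)
            if all(c in df.columns for c in tern_cols)
            else None
        )
        profiles.append(
            PanelProfile(compound_id=str(row["compound_id"]), delta=delta, ternary=ternary)
        )
    return profiles


def write_latents(
    compound_ids: list[str], latents: np.ndarray, path: str | Path
) -> None:
    df = pd.DataFrame(latents, columns=[f"z{j}" for j in range(latents.shape[1])])
    df.insert(0, "compound_id", compound_ids)
    df.to_csv(path, index=False)


def read_latents(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise SchemaError("latents file must contain a compound_id column")
    ids = df["compound_id"].astype(str).tolist()
    values = df.drop(columns="compound_id").to_numpy(dtype=float)
    return ids, values


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
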