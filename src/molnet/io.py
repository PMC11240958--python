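"""Molecule tables and the 12-component descriptor vector.

Molecules enter as rows of a CSV with a SMILES column (the DeepChem
``bace.csv`` dialect: SMILES under ``mol``).  Each molecule is summarised by
a fixed-order vector of 12 descriptors:

==============  =======================================================
column          meaning (units)
==============  =======================================================
molecular_mass  molecular weight (amu)
mmff_energy     MMFF94 conformer energy minus a reference (kcal/mol)
clogp           Crippen calculated logP (unitless)
mr              Crippen molar refractivity (unitless)
eccentricity    geometric eccentricity of the 3D conformer, in [0, 1]
kappa1..kappa3  Kier kappa shape indices (unitless)
sa_score        synthetic-accessibility score (unitless)
tpsa            topological polar surface area (A^2)
ac2d_entropy    Shannon entropy of the 2D autocorrelation vector
ac3d_entropy    Shannon entropy of the 3D autocorrelation vector
==============  =======================================================

Raw per-molecule quantities (MMFF energy, Crippen contributions, kappa
indices, TPSA, autocorrelation vectors, fingerprints) come from a toolkit
adapter; the bespoke post-processing applied here is the reference
subtraction of the MMFF energies and the Shannon entropies of the
autocorrelation vectors.
"""

from __future__ import annotations

import csv
import logging
import math
import os
import sys
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed column order of the descriptor table.
DESCRIPTOR_COLUMNS = (
    "molecular_mass",
    "mmff_energy",
    "clogp",
    "mr",
    "eccentricity",
    "kappa1",
    "kappa2",
    "kappa3",
    "sa_score",
    "tpsa",
    "ac2d_entropy",
    "ac3d_entropy",
)


@dataclass
class MoleculeRecord:
    """One molecule: identifier, SMILES, and (once computed) fingerprint
    and descriptor vector."""

    id: str
    smiles: str
    fingerprint: Optional[np.ndarray] = None
    descriptors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"molecule {self.id!r}: empty SMILES")


@dataclass
class DescriptorTable:
    """n x 12 descriptor matrix with molecule ids, fixed column order."""

    ids: Sequence[str]
    values: np.ndarray  # (n, 12)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(DESCRIPTOR_COLUMNS):
            raise ValueError(
                f"descriptor table must have {len(DESCRIPTOR_COLUMNS)} columns, "
                f"got shape {self.values.shape}"
            )
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("id count does not match row count")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite descriptor: row {self.ids[bad[0]]!r}, "
                f"column {DESCRIPTOR_COLUMNS[bad[1]]!r}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(DESCRIPTOR_COLUMNS))
        df.insert(0, "id", list(self.ids))
        return df

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "DescriptorTable":
        df = pd.read_csv(path)
        missing = [c for c in DESCRIPTOR_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"descriptor CSV missing columns: {missing}")
        return cls(
            ids=[str(x) for x in df["id"]],
            values=df[list(DESCRIPTOR_COLUMNS)].to_numpy(dtype=float),
        )


class AdapterError(RuntimeError):
    """Toolkit failure on a specific molecule."""


def read_molecule_table(
    path: str,
    smiles_column: str = "mol",
    id_column: Optional[str] = None,
) -> list[MoleculeRecord]:
    """Read a molecule CSV into records, preserving file order.

    Rows whose SMILES cannot be parsed are excluded with a logged warning.
    Ids default to the 0-based row index when ``id_column`` is absent.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or smiles_column not in reader.fieldnames:
            raise KeyError(
                f"column {smiles_column!r} not found in {path} "
                f"(header: {reader.fieldnames})"
            )
        if id_column is not None and id_column not in reader.fieldnames:
            raise KeyError(f"id column {id_column!r} not found in {path}")
        RDLogger.DisableLog("rdApp.error")
        try:
            records: list[MoleculeRecord] = []
            for i, row in enumerate(reader):
                smiles = row[smiles_column]
                mol_id = row[id_column] if id_column is not None else str(i)
                if not smiles or Chem.MolFromSmiles(smiles) is None:
                    logger.warning(
                        "excluding molecule %r (row %d): unparsable SMILES %r",
                        mol_id, i, smiles,
                    )
                    continue
                records.append(MoleculeRecord(id=mol_id, smiles=smiles))
        finally:
            RDLogger.EnableLog("rdApp.error")
    return records


def normalize_mmff_energy(
    raw_energies: np.ndarray,
    strategy: str = "min-reference",
    reference_index: int = 0,
) -> np.ndarray:
    """Subtract a reference structure's energy from each raw MMFF energy.

    ``min-reference`` uses the minimum energy of the set (output is
    non-negative with minimum exactly 0); ``index-reference`` subtracts
    the energy at ``reference_index``.  Pairwise differences are preserved
    exactly.
    """
    e = np.asarray(raw_energies, dtype=float)
    if e.size == 0:
        raise ValueError("cannot normalize an empty energy vector")
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite raw MMFF energy")
    if strategy == "min-reference":
        ref = e.min()
    elif strategy == "index-reference":
        ref = e[reference_index]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return e - ref


def shannon_entropy(v: np.ndarray, base: float = math.e) -> float:
    """Shannon entropy of the absolute-value-normalised vector ``v``.

    p_i = |v_i| / sum |v_j|;  H = -sum_{p_i>0} p_i log_base p_i.
    Scale- and permutation-invariant; 0 for a point mass, log_base(len(v))
    for a uniform vector.
    """
    v = np.abs(np.asarray(v, dtype=float))
    if v.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    if base <= 1:
        raise ValueError("entropy base must be > 1")
    total = v.sum()
    if total == 0:
        raise ValueError("entropy undefined for an all-zero vector")
    p = v[v > 0] / total
    return float(-(p * (np.log(p) / math.log(base))).sum())


class RDKitAdapter:
    """Toolkit adapter: raw per-molecule computations via RDKit.

    3D-dependent quantities (MMFF energy, geometric eccentricity, 3D
    autocorrelation) use a single ETKDG conformer embedded with a fixed
    seed, so the adapter is deterministic for a fixed molecule and seed.
    Parsed molecules and conformers are cached per SMILES.
    """

    def __init__(self, conformer_seed: int = 2024):
        self.conformer_seed = int(conformer_seed)
        self._cache: dict[str, object] = {}

    # -- internals -----------------------------------------------------
    def _mol(self, smiles: str):
        from rdkit import Chem

        key = ("2d", smiles)
        if key not in self._cache:
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise AdapterError(f"unparsable SMILES: {smiles!r}")
            self._cache[key] = mol
        return self._cache[key]

    def _mol3d(self, smiles: str):
        from rdkit import Chem
        from rdkit.Chem import AllChem

        key = ("3d", smiles)
        if key not in self._cache:
            mol = Chem.AddHs(self._mol(smiles))
            params = AllChem.ETKDGv3()
            params.randomSeed = self.conformer_seed
            if AllChem.EmbedMolecule(mol, params) != 0:
                # fall back to random coordinates for pathological inputs
                params.useRandomCoords = True
                if AllChem.EmbedMolecule(mol, params) != 0:
                    raise AdapterError(f"conformer embedding failed: {smiles!r}")
            self._cache[key] = mol
        return self._cache[key]

    # -- raw quantities ------------------------------------------------
    def molecular_mass(self, smiles: str) -> float:
        from rdkit.Chem import Descriptors

        return float(Descriptors.MolWt(self._mol(smiles)))

    def raw_mmff_energy(self, smiles: str) -> float:
        from rdkit.Chem import AllChem

        mol = self._mol3d(smiles)
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is None:
            raise AdapterError(f"no MMFF parameters for {smiles!r}")
        ff = AllChem.MMFFGetMoleculeForceField(mol, props)
        return float(ff.CalcEnergy())

    def clogp(self, smiles: str) -> float:
        from rdkit.Chem import Crippen

        return float(Crippen.MolLogP(self._mol(smiles)))

    def mr(self, smiles: str) -> float:
        from rdkit.Chem import Crippen

        return float(Crippen.MolMR(self._mol(smiles)))

    def eccentricity(self, smiles: str) -> float:
        from rdkit.Chem import Descriptors3D

        return float(Descriptors3D.Eccentricity(self._mol3d(smiles)))

    def kappa_indices(self, smiles: str) -> tuple[float, float, float]:
        from rdkit.Chem import rdMolDescriptors as rd

        mol = self._mol(smiles)
        return (
            float(rd.CalcKappa1(mol)),
            float(rd.CalcKappa2(mol)),
            float(rd.CalcKappa3(mol)),
        )

    def sa_score(self, smiles: str) -> float:
        sascorer = _load_sascorer()
        return float(sascorer.calculateScore(self._mol(smiles)))

    def tpsa(self, smiles: str) -> float:
        from rdkit.Chem import rdMolDescriptors as rd

        return float(rd.CalcTPSA(self._mol(smiles)))

    def autocorrelation_2d(self, smiles: str) -> np.ndarray:
        from rdkit.Chem import rdMolDescriptors as rd

        return np.asarray(rd.CalcAUTOCORR2D(self._mol(smiles)), dtype=float)

    def autocorrelation_3d(self, smiles: str) -> np.ndarray:
        from rdkit.Chem import rdMolDescriptors as rd

        return np.asarray(rd.CalcAUTOCORR3D(self._mol3d(smiles)), dtype=float)

    def fingerprint(self, smiles: str, kind: str = "morgan", length: int = 2048) -> np.ndarray:
        from rdkit.Chem import rdFingerprintGenerator as rfg

        if length <= 0:
            raise ValueError("fingerprint length must be positive")
        if kind == "morgan":
            gen = rfg.GetMorganGenerator(radius=2, fpSize=length)
        elif kind == "rdkit":
            gen = rfg.GetRDKitFPGenerator(fpSize=length)
        else:
            raise ValueError(f"unknown fingerprint kind {kind!r}")
        return gen.GetFingerprintAsNumPy(self._mol(smiles)).astype(np.uint8)


def _load_sascorer():
    """Import RDKit's contrib synthetic-accessibility scorer."""
    try:
        import sascorer  # type: ignore
    except ImportError:
        from rdkit import RDConfig

        sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
        import sascorer  # type: ignore
    return sascorer


def compute_descriptor_table(
    molecules: Sequence[MoleculeRecord],
    adapter: Optional[RDKitAdapter] = None,
    mmff_strategy: str = "min-reference",
    entropy_base: float = math.e,
) -> DescriptorTable:
    """Assemble the 12-column descriptor table for a set of molecules.

    The MMFF column is normalised across the input set via
    :func:`normalize_mmff_energy`; the autocorrelation entropy columns are
    computed via :func:`shannon_entropy`.  Adapter failures propagate with
    the molecule id attached.
    """
    if adapter is None:
        adapter = RDKitAdapter()
    n = len(molecules)
    if n == 0:
        raise ValueError("no molecules")
    raw_energy = np.empty(n)
    rows = np.empty((n, len(DESCRIPTOR_COLUMNS)))
    for i, rec in enumerate(molecules):
        try:
            s = rec.smiles
            raw_energy[i] = adapter.raw_mmff_energy(s)
            k1, k2, k3 = adapter.kappa_indices(s)
            rows[i] = [
                adapter.molecular_mass(s),
                0.0,  # mmff filled after normalisation
                adapter.clogp(s),
                adapter.mr(s),
                adapter.eccentricity(s),
                k1,
                k2,
                k3,
                adapter.sa_score(s),
                adapter.tpsa(s),
                shannon_entropy(adapter.autocorrelation_2d(s), base=entropy_base),
                shannon_entropy(adapter.autocorrelation_3d(s), base=entropy_base),
            ]
        except Exception as exc:  # attach the offending molecule id
            raise AdapterError(f"descriptor computation failed for {rec.id!r}: {exc}") from exc
    rows[:, 1] = normalize_mmff_energy(raw_energy, strategy=mmff_strategy)
    table = DescriptorTable(ids=[m.id for m in molecules], values=rows)
    for rec, desc in zip(molecules, rows):
        rec.descriptors = desc
    return table


def compute_fingerprints(
    molecules: Sequence[MoleculeRecord],
    adapter: Optional[RDKitAdapter] = None,
    kind: str = "morgan",
    length: int = 2048,
) -> np.ndarray:
    """Compute an (n, L) 0/1 fingerprint matrix and store it on the records."""
    if adapter is None:
        adapter = RDKitAdapter()
    if length <= 0:
        raise ValueError("fingerprint length must be positive")
    fps = np.empty((len(molecules), length), dtype=np.uint8)
    for i, rec in enumerate(molecules):
        try:
            fps[i] = adapter.fingerprint(rec.smiles, kind=kind, length=length)
        except Exception as exc:
            raise AdapterError(f"fingerprint failed for {rec.id!r}: {exc}") from exc
        rec.fingerprint = fps[i]
    return fps
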