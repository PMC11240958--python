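"""Synthetic molecule-like records with planted cluster structure.

Each of K clusters has a descriptor centroid (drawn inside realistic
per-column ranges: mass ~200-800 amu, TPSA ~50-250 A^2, eccentricity
0.8-1.0, ...), a fingerprint template, and a SMILES-like template string.
A molecule is its cluster's centroid plus diagonal Gaussian noise, the
template with independent bit flips at rate epsilon, and the template
string with independent character substitutions at rate rho (substitution
only by default, so the expected edit distance grows linearly with rho;
an indel mode is available).  All four distance functions therefore carry
the planted structure at low noise.

The pseudo-SMILES strings are not chemically valid; they feed only the
Levenshtein stage.  Fixed seed -> byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .communities import Partition
from .io import DESCRIPTOR_COLUMNS

#: Per-column (low, high) centroid ranges spanning realistic magnitudes.
DEFAULT_CENTROID_RANGES: dict[str, tuple[float, float]] = {
    "molecular_mass": (200.0, 800.0),
    "mmff_energy": (0.0, 300.0),
    "clogp": (-2.0, 8.0),
    "mr": (50.0, 200.0),
    "eccentricity": (0.8, 1.0),
    "kappa1": (5.0, 40.0),
    "kappa2": (3.0, 20.0),
    "kappa3": (2.0, 12.0),
    "sa_score": (1.0, 6.0),
    "tpsa": (50.0, 250.0),
    "ac2d_entropy": (2.0, 6.0),
    "ac3d_entropy": (2.0, 6.0),
}

SMILES_ALPHABET = "CcNnOoSs()=#123[]+-F"


@dataclass
class SyntheticSpec:
    """Generator settings: cluster layout, noise levels, seed."""

    sizes: Sequence[int] = (50, 50, 50, 50)
    centroid_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_CENTROID_RANGES))
    noise_sd_fraction: float = 0.02  # within-cluster sd as fraction of range
    fingerprint_length: int = 256
    template_density: float = 0.3
    bit_flip_rate: float = 0.02
    alphabet: str = SMILES_ALPHABET
    template_length: int = 40
    edit_rate: float = 0.05
    indel_mode: bool = False
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def n(self) -> int:
        return int(sum(self.sizes))

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sizes):
            raise ValueError("cluster sizes must be positive")
        if not (0 <= self.bit_flip_rate < 1):
            raise ValueError("bit_flip_rate must lie in [0, 1)")
        if not (0 <= self.edit_rate < 1):
            raise ValueError("edit_rate must lie in [0, 1)")
        missing = [c for c in DESCRIPTOR_COLUMNS if c not in self.centroid_ranges]
        if missing:
            raise ValueError(f"centroid range missing for: {missing}")


@dataclass
class SyntheticSet:
    """Generated records plus the planted partition."""

    ids: list[str]
    smiles: list[str]
    fingerprints: np.ndarray  # (n, L) uint8
    descriptors: np.ndarray  # (n, 12)
    planted: Partition

    @property
    def n(self) -> int:
        return len(self.ids)

    def descriptor_table(self):
        from .io import DescriptorTable

        return DescriptorTable(ids=self.ids, values=self.descriptors)

    def to_csv(self, path: str) -> None:
        """Write in the molecule-table dialect (columns id, mol, cluster)."""
        pd.DataFrame({
            "id": self.ids,
            "mol": self.smiles,
            "cluster": self.planted.labels,
        }).to_csv(path, index=False)


def _mutate_string(rng: np.random.Generator, template: str, spec: SyntheticSpec) -> str:
    chars = list(template)
    alphabet = spec.alphabet
    if spec.indel_mode:
        out = []
        for ch in chars:
            r = rng.random()
            if r < spec.edit_rate / 3:
                continue  # deletion
            if r < 2 * spec.edit_rate / 3:
                out.append(alphabet[rng.integers(len(alphabet))])  # substitution
            else:
                out.append(ch)
            if rng.random() < spec.edit_rate / 3:
                out.append(alphabet[rng.integers(len(alphabet))])  # insertion
        return "".join(out) or alphabet[0]
    hits = rng.random(len(chars)) < spec.edit_rate
    for pos in np.flatnonzero(hits):
        chars[pos] = alphabet[rng.integers(len(alphabet))]
    return "".join(chars)


def generate_synthetic_molecules(spec: SyntheticSpec) -> SyntheticSet:
    """Draw a planted-cluster set of molecule-like records.

    Cluster centroids are uniform within the configured per-column
    ranges; rows are centroid + N(0, sd^2) with
    sd = noise_sd_fraction * column range.  Fingerprint templates are
    Bernoulli(template_density) with at least one set bit guaranteed.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_clusters
    cols = [spec.centroid_ranges[c] for c in DESCRIPTOR_COLUMNS]
    lows = np.array([c[0] for c in cols])
    highs = np.array([c[1] for c in cols])
    spans = highs - lows
    centroids = lows + rng.random((K, len(cols))) * spans
    sds = spec.noise_sd_fraction * spans

    fp_templates = (rng.random((K, spec.fingerprint_length))
                    < spec.template_density).astype(np.uint8)
    for k in range(K):  # Tanimoto needs a non-empty fingerprint
        if fp_templates[k].sum() == 0:
            fp_templates[k, rng.integers(spec.fingerprint_length)] = 1
    str_templates = [
        "".join(spec.alphabet[i] for i in rng.integers(len(spec.alphabet),
                                                       size=spec.template_length))
        for _ in range(K)
    ]

    ids: list[str] = []
    smiles: list[str] = []
    labels: list[int] = []
    fps = np.empty((spec.n, spec.fingerprint_length), dtype=np.uint8)
    desc = np.empty((spec.n, len(cols)))
    row = 0
    for k, size in enumerate(spec.sizes):
        for _ in range(size):
            ids.append(f"syn{row}")
            labels.append(k)
            desc[row] = centroids[k] + rng.standard_normal(len(cols)) * sds
            flips = rng.random(spec.fingerprint_length) < spec.bit_flip_rate
            fp = fp_templates[k] ^ flips.astype(np.uint8)
            if fp.sum() == 0:
                fp[rng.integers(spec.fingerprint_length)] = 1
            fps[row] = fp
            smiles.append(_mutate_string(rng, str_templates[k], spec))
            row += 1
    planted = Partition(ids=list(ids), labels=np.array(labels))
    return SyntheticSet(ids=ids, smiles=smiles, fingerprints=fps,
                        descriptors=desc, planted=planted)
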