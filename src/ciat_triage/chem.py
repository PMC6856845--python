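"""Molecular representations: fingerprints, Tanimoto similarity, PAINS matching.

Compounds are represented as ECFP4-style Morgan circular fingerprints
(radius 2) hashed to 1024 binary bits.  Substructure alerts for pan-assay
interference compounds (PAINS) are applied through a 480-pattern SMARTS
catalog; by default the catalog bundled with RDKit (families A, B and C
merged) is used, but any file of ``SMARTS<TAB>name`` lines can be loaded
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

RDLogger.DisableLog("rdApp.*")

FINGERPRINT_RADIUS = 2
FINGERPRINT_BITS = 1024
PAINS_CATALOG_SIZE = 480


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed.

    Records carrying unparseable structures are discarded by callers rather
    than silently imputed.
    """


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`StructureParseError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise StructureParseError("empty structure string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"could not parse structure: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def compute_fingerprint(
    smiles: str | Chem.Mol,
    radius: int = FINGERPRINT_RADIUS,
    n_bits: int = FINGERPRINT_BITS,
) -> np.ndarray:
    """Morgan circular fingerprint as a dense 0/1 ``uint8`` vector.

    A pure function of the structure: the same SMILES always yields the
    same bit vector.
    """
    mol = smiles if isinstance(smiles, Chem.Mol) else mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)


def fingerprint_matrix(
    smiles: Sequence[str],
    radius: int = FINGERPRINT_RADIUS,
    n_bits: int = FINGERPRINT_BITS,
) -> np.ndarray:
    """Stack fingerprints for a list of parseable SMILES into an (n, bits) matrix."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(smiles), n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles):
        out[i] = gen.GetFingerprintAsNumPy(mol_from_smiles(smi))
    return out


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| between two bit vectors.

    Defined as 0.0 when both vectors are empty (the 0/0 case); empty
    fingerprints are pathological for real molecules.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(np.logical_and(a, b)))
    union = int(np.count_nonzero(np.logical_or(a, b)))
    if union == 0:
        return 0.0
    return inter / union


def bulk_tanimoto(query: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Tanimoto of one fingerprint against every row of a fingerprint matrix."""
    query = np.asarray(query, dtype=np.int64)
    matrix = np.asarray(matrix, dtype=np.int64)
    if matrix.ndim != 2 or matrix.shape[1] != query.shape[0]:
        raise ValueError("matrix columns must match query length")
    inter = matrix @ query
    union = matrix.sum(axis=1) + query.sum() - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return tc


def cross_tanimoto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-by-all Tanimoto matrix between two fingerprint matrices."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1), 0.0)


@dataclass
class SubstructureCatalog:
    """A named set of SMARTS substructure alerts.

    Backed either by compiled SMARTS queries (file-loaded catalogs) or by an
    RDKit ``FilterCatalog`` (the bundled PAINS set).
    """

    entries: list[tuple[str, str | None]] = field(default_factory=list)
    _queries: list[tuple[str, Chem.Mol]] = field(default_factory=list, repr=False)
    _filter_catalog: FilterCatalog | None = field(default=None, repr=False)

    def __len__(self) -> int:
        if self._filter_catalog is not None:
            return self._filter_catalog.GetNumEntries()
        return len(self._queries)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def match(self, smiles: str | Chem.Mol) -> list[str]:
        """Names of every catalog pattern with a substructure match.

        A compound is PAINS-predicted-CIAT exactly when this list is
        non-empty.  Parse errors propagate to the caller.
        """
        mol = smiles if isinstance(smiles, Chem.Mol) else mol_from_smiles(smiles)
        if self._filter_catalog is not None:
            return [e.GetDescription() for e in self._filter_catalog.GetMatches(mol)]
        return [name for name, query in self._queries if mol.HasSubstructMatch(query)]

    def matches_any(self, smiles: str | Chem.Mol) -> bool:
        mol = smiles if isinstance(smiles, Chem.Mol) else mol_from_smiles(smiles)
        if self._filter_catalog is not None:
            return self._filter_catalog.HasMatch(mol)
        return any(mol.HasSubstructMatch(q) for _, q in self._queries)


def _bundled_pains() -> SubstructureCatalog:
    params = FilterCatalogParams()
    params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
    cat = FilterCatalog(params)
    entries = [
        (cat.GetEntryWithIdx(i).GetDescription(), None)
        for i in range(cat.GetNumEntries())
    ]
    return SubstructureCatalog(entries=entries, _filter_catalog=cat)


def load_pains_catalog(source: str | Path | None = None) -> SubstructureCatalog:
    """Load the PAINS alert catalog.

    With ``source=None`` the RDKit-bundled PAINS set (families A, B, C
    merged; 480 patterns, e.g. ``quinone_A(370)``) is returned.  Otherwise
    ``source`` is a text file with one ``SMARTS<TAB or space>name`` entry
    per line; ``#`` comment lines and blank lines are ignored.
    """
    if source is None:
        cat = _bundled_pains()
        if len(cat) != PAINS_CATALOG_SIZE:  # pragma: no cover - toolkit guard
            raise RuntimeError(
                f"bundled PAINS catalog has {len(cat)} entries, "
                f"expected {PAINS_CATALOG_SIZE}"
            )
        return cat
    return load_smarts_catalog(source)


def load_smarts_catalog(path: str | Path) -> SubstructureCatalog:
    """Load a SMARTS catalog file (one pattern + name per line)."""
    lines = Path(path).read_text().splitlines()
    entries: list[tuple[str, str | None]] = []
    queries: list[tuple[str, Chem.Mol]] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'SMARTS name', got {raw!r}")
        smarts, name = parts[0], parts[1].strip()
        if name in seen:
            raise ValueError(f"line {lineno}: duplicate pattern name {name!r}")
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"line {lineno}: could not parse SMARTS for {name!r}")
        seen.add(name)
        entries.append((name, smarts))
        queries.append((name, query))
    if not entries:
        raise ValueError(f"no patterns found in catalog file {path}")
    return SubstructureCatalog(entries=entries, _queries=queries)


def match_pains(
    smiles: str | Chem.Mol, catalog: SubstructureCatalog
) -> list[str]:
    """All catalog pattern names matching the given structure."""
    return catalog.match(smiles)
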