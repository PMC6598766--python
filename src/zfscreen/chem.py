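"""Structure handling for screening libraries.

Standardisation, Morgan/ECFP4 fingerprints, Tanimoto similarity,
Bemis-Murcko scaffold analysis and InChIKey-based duplicate detection.

All structure chemistry is delegated to RDKit; this module fixes the
conventions (largest organic fragment, charge neutralisation, binary
2048-bit fingerprints of radius 2) and the container types the rest of
the pipeline consumes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed.

    Carries the offending string in ``smiles``.
    """

    def __init__(self, smiles: str, context: str = ""):
        self.smiles = smiles
        msg = f"unparseable SMILES: {smiles!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


@dataclass(frozen=True)
class Compound:
    """One library entry: identity, plate position and structure."""

    compound_id: str
    library_id: str
    plate: str
    well: str
    name: str
    smiles: str
    identity_key: str | None = None

    def __post_init__(self):
        if not WELL_RE.match(self.well):
            raise ValueError(
                f"well {self.well!r} does not match row-letter + 2-digit column"
            )


@dataclass(frozen=True)
class Fingerprint:
    """Binary substructure fingerprint as an explicit set of on-bit indices."""

    bits: frozenset[int]
    n_bits: int = 2048
    radius: int = 2

    def __post_init__(self):
        if self.bits and not all(0 <= b < self.n_bits for b in self.bits):
            raise ValueError("bit index outside [0, n_bits)")


@dataclass
class SimilarityMatrix:
    """Symmetric all-pairs Tanimoto matrix with the compound ids it indexes."""

    compound_ids: list[str]
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.compound_ids)


@dataclass
class ScaffoldSummary:
    n_compounds: int
    n_scaffolds: int
    n_singleton_scaffolds: int
    scaffold_to_members: dict[str, list[str]]
    n_acyclic: int
    n_parse_failures: int = 0
    failed_compound_ids: list[str] = field(default_factory=list)


_normalizer = rdMolStandardize.Normalizer()
_fragment_chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()


def _parse(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise StructureParseError(smiles, "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles)
    return mol


def standardize_structure(smiles: str) -> str:
    """Return the canonical SMILES of the standardised structure.

    Standardisation keeps the largest organic fragment (dropping
    counter-ions and solvates), normalises functional-group
    representations and neutralises charges where valence permits.
    No tautomer canonicalisation is applied. The operation is
    idempotent: standardising an already standard SMILES is a no-op.
    """
    mol = _parse(smiles)
    mol = _normalizer.normalize(mol)
    mol = _fragment_chooser.choose(mol)
    mol = _uncharger.uncharge(mol)
    return Chem.MolToSmiles(mol)


def inchikey(smiles: str) -> str | None:
    """27-character InChIKey of a standardised SMILES, or None on failure."""
    try:
        mol = _parse(smiles)
    except StructureParseError:
        return None
    key = Chem.MolToInchiKey(mol)
    return key or None


_fp_generators: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _fp_generators:
        _fp_generators[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _fp_generators[key]


def compute_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Morgan fingerprint of the given radius (radius 2 is ECFP4-equivalent)."""
    mol = _parse(smiles)
    bv = _generator(radius, n_bits).GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| of two bit sets.

    Both-empty input is defined as 0.0 (degenerate case, logged) so that
    all-pairs matrices stay total.
    """
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprints have different n_bits")
    union = len(a.bits | b.bits)
    if union == 0:
        logger.warning("tanimoto of two empty fingerprints; returning 0.0")
        return 0.0
    return len(a.bits & b.bits) / union


def similarity_matrix(
    compounds: list[Compound], radius: int = 2, n_bits: int = 2048
) -> SimilarityMatrix:
    """All-pairs Tanimoto matrix over a compound list.

    Raises if any structure fails to parse, naming the offending
    compound_ids, so a partial matrix is never produced silently.
    """
    fps, bad = [], []
    for c in compounds:
        try:
            fps.append(compute_fingerprint(c.smiles, radius=radius, n_bits=n_bits))
        except StructureParseError:
            bad.append(c.compound_id)
    if bad:
        raise StructureParseError(
            ",".join(bad), f"{len(bad)} unparseable compounds in similarity_matrix"
        )
    n = len(fps)
    values = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tanimoto(fps[i], fps[j])
        if not fps[i].bits:
            values[i, i] = 0.0
    return SimilarityMatrix([c.compound_id for c in compounds], values)


def bemis_murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold (ring systems + linkers, side chains pruned).

    Acyclic molecules have no ring system and return the empty string.
    """
    mol = _parse(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold) if scaffold.GetNumAtoms() else ""


def scaffold_summary(compounds: list[Compound]) -> ScaffoldSummary:
    """Tally Bemis-Murcko scaffolds over a library.

    Acyclic compounds (empty scaffold) are counted separately and do not
    contribute a scaffold; a singleton scaffold has exactly one member.
    Parse failures are counted and reported rather than raised.
    """
    members: dict[str, list[str]] = {}
    n_acyclic = 0
    failed: list[str] = []
    for c in compounds:
        try:
            scaf = bemis_murcko_scaffold(c.smiles)
        except StructureParseError:
            failed.append(c.compound_id)
            continue
        if scaf == "":
            n_acyclic += 1
        else:
            members.setdefault(scaf, []).append(c.compound_id)
    return ScaffoldSummary(
        n_compounds=len(compounds) - len(failed),
        n_scaffolds=len(members),
        n_singleton_scaffolds=sum(1 for v in members.values() if len(v) == 1),
        scaffold_to_members=members,
        n_acyclic=n_acyclic,
        n_parse_failures=len(failed),
        failed_compound_ids=failed,
    )


def find_duplicates(
    lib_a: list[Compound], lib_b: list[Compound]
) -> list[tuple[str, str]]:
    """Cross-library duplicate pairs by identical full InChIKey.

    Compounds with a null identity_key are skipped with a warning.
    Pairs are returned sorted by (key, id_a, id_b) for determinism.
    """
    by_key: dict[str, list[str]] = {}
    for c in lib_a:
        if c.identity_key is None:
            logger.warning("skipping %s: no identity key", c.compound_id)
            continue
        by_key.setdefault(c.identity_key, []).append(c.compound_id)
    pairs = []
    for c in lib_b:
        if c.identity_key is None:
            logger.warning("skipping %s: no identity key", c.compound_id)
            continue
        for other in by_key.get(c.identity_key, ()):
            pairs.append((c.identity_key, other, c.compound_id))
    pairs.sort()
    return [(a, b) for _, a, b in pairs]


def make_compound(
    compound_id: str,
    library_id: str,
    plate: str,
    well: str,
    name: str,
    smiles: str,
) -> Compound:
    """Build a Compound with standardised SMILES and InChIKey populated.

    identity_key is None exactly when the SMILES fails to parse (the raw
    string is kept so the failure is reportable downstream).
    """
    try:
        std = standardize_structure(smiles)
        key = inchikey(std)
    except StructureParseError:
        std, key = smiles, None
    return Compound(compound_id, library_id, plate, well, name, std, key)
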