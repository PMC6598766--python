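"""Synthetic screening data.

Generates two overlapping compound libraries with planted scaffold
families and activity classes, then simulates the whole assay cascade
(primary three-embryo wells, retests, counter screen, strong-allele
re-screen) with ordinal scoring noise and embryo death, so every
pipeline stage can be exercised and its recovery of the planted ground
truth measured.

Chemistry is template-grafted SMILES: each family is a fixed core with a
substitution slot and a list of substituents, so family members share a
large common substructure and within-family Tanimoto similarity is high
by construction. Fillers are random chain-plus-ring singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import triage as tri
from .chem import Compound, make_compound
from .triage import Assay, Category, MbpClass, MechanismClass, TriageRecord, WellResult

# Activity classes planted in the library.
CLASSES = (
    "downstream_agonist",
    "receptor_agonist",
    "ear_specific",
    "transcription_inhibitor",
    "inactive",
    "toxic",
)

# Scaffold families: (name, core SMILES with one {R} slot, substituents).
# Cores are large relative to the substituents so that decorated members
# stay well above the 0.5 Tanimoto network threshold.
DEFAULT_FAMILIES: list[tuple[str, str, list[str]]] = [
    (
        "dihydropyridine",
        "CC1=C(C(=O)OC)C(c2ccc({R})cc2)C(C(=O)OC)=C(C)N1",
        ["[N+](=O)[O-]", "Cl", "F", "Br", "C", "OC", "CC", "O", "N",
         "C(F)(F)F", "C#N", "OCC", "CCC", "I"],
    ),
    (
        "xanthine",
        "CN1C=NC2=C1C(=O)N({R})C(=O)N2C",
        ["C", "CC", "CCC", "CC(C)C", "CCCC", "CCO", "CCN", "CCOC",
         "CCCCC", "CC(C)CC", "CCCN", "CCC(C)C"],
    ),
    (
        "flavone",
        "O=c1cc(-c2ccc({R})cc2)oc2ccccc12",
        ["O", "OC", "Cl", "F", "C", "CC", "OCC", "N", "Br", "C(F)(F)F",
         "C#N", "CCC"],
    ),
    (
        "steroid",
        "CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O{R}",
        ["C(C)=O", "C(=O)CC", "C(=O)CCC", "C", "CC", "C(=O)COC",
         "C(=O)C(C)C", "C(=O)c3ccccc3", "CCO", "C(=O)CCl", "C(C)C",
         "C(=O)CCCC"],
    ),
    (
        "benzimidazole",
        "c1ccc2[nH]c(-c3ccc({R})cc3)nc2c1",
        ["C", "CC", "Cl", "F", "Br", "OC", "O", "N", "C(F)(F)F",
         "C#N", "OCC", "CCC"],
    ),
    (
        "quinolinone",
        "O=C(O)c1cn({R})c2ccc(F)cc2c1=O",
        ["CC", "C", "CCC", "C3CC3", "CCO", "CC(C)C", "CCCC", "CCF",
         "Cc3ccccc3", "CCN", "CCOC", "C(C)C"],
    ),
]

# Per-class base scores for each assay at zero noise.
BASE_SCORES: dict[str, dict[Assay, int]] = {
    "downstream_agonist": {Assay.VCANB_TB233C: 0, Assay.MBP_TB233C: 3, Assay.VCANB_FR24: 0},
    "receptor_agonist": {Assay.VCANB_TB233C: 0, Assay.MBP_TB233C: 3, Assay.VCANB_FR24: 3},
    "ear_specific": {Assay.VCANB_TB233C: 0, Assay.MBP_TB233C: 1, Assay.VCANB_FR24: 3},
    "transcription_inhibitor": {Assay.VCANB_TB233C: 0, Assay.MBP_TB233C: 0, Assay.VCANB_FR24: 0},
    "inactive": {Assay.VCANB_TB233C: 3, Assay.MBP_TB233C: 1, Assay.VCANB_FR24: 3},
    "toxic": {Assay.VCANB_TB233C: 3, Assay.MBP_TB233C: 1, Assay.VCANB_FR24: 3},
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic screen.

    Defaults emulate the screened design: two libraries of 1000 and 2000
    compounds with 5% of the smaller library duplicated into the larger,
    a mostly-inactive library (91% inactive, 5% toxic, 4% split over the
    four active classes), ordinal scoring noise of 10% per adjacent
    score step, a 0.5% background embryo death rate and near-certain
    death under toxic compounds.
    """

    n_compounds: tuple[int, int] = (1000, 2000)
    duplicate_fraction: float = 0.05
    scaffold_families: list[tuple[str, str, list[str]]] = field(
        default_factory=lambda: [f for f in DEFAULT_FAMILIES]
    )
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "downstream_agonist": 0.01,
            "receptor_agonist": 0.01,
            "ear_specific": 0.01,
            "transcription_inhibitor": 0.01,
            "inactive": 0.91,
            "toxic": 0.05,
        }
    )
    # weights over CLASSES for the class planted on a whole family
    family_class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "downstream_agonist": 0.25,
            "receptor_agonist": 0.25,
            "ear_specific": 0.15,
            "transcription_inhibitor": 0.10,
            "inactive": 0.25,
            "toxic": 0.0,
        }
    )
    sar_coherence: float = 0.8
    score_noise: float = 0.1  # probability mass moved to adjacent scores
    death_prob: dict[str, float] = field(
        default_factory=lambda: {c: 0.005 for c in CLASSES} | {"toxic": 0.9}
    )
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")

    @classmethod
    def zero_noise(cls, **kwargs) -> "SynthConfig":
        """Noise-free conditions: deterministic scores, toxic kills all."""
        cfg = cls(**kwargs)
        cfg.score_noise = 0.0
        cfg.death_prob = {c: 0.0 for c in CLASSES} | {"toxic": 1.0}
        return cfg


@dataclass
class GroundTruth:
    class_of: dict[str, str]
    family_of: dict[str, str]  # compound_id -> family name ("" for fillers)
    duplicate_pairs: list[tuple[str, str]]


_FILLER_RINGS = [
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "C1CCCCC1", "c1ccsc1",
    "c1ccoc1", "C1CCNCC1", "C1CCOC1", "c1cccnc1", "C1CCCC1",
]
_CHAIN_ATOMS = ["C", "C", "C", "C", "N", "O"]


def _random_chain(rng: np.random.Generator, min_len: int = 1, max_len: int = 8) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    atoms = [str(rng.choice(_CHAIN_ATOMS)) for _ in range(length)]
    # occasional methyl branch keeps chains diverse; always valid mid-chain
    out = atoms[0]
    for a in atoms[1:]:
        if rng.random() < 0.2:
            out += "(C)"
        out += a
    return out


def _filler_smiles(rng: np.random.Generator) -> str:
    chain = _random_chain(rng)
    if rng.random() < 0.15:  # acyclic filler
        return chain
    return chain + str(rng.choice(_FILLER_RINGS))


def _wells(prefix: str):
    """Yield (plate, well) positions: compounds in columns 2-11, rows A-H."""
    plate_no = 1
    while True:
        plate = f"{prefix}{plate_no:02d}"
        for col in range(2, 12):
            for row in "ABCDEFGH":
                yield plate, f"{row}{col:02d}"
        plate_no += 1


def _draw(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def generate_library(cfg: SynthConfig) -> tuple[list[Compound], GroundTruth]:
    """Build both libraries with planted families, classes and duplicates.

    Family members are core+substituent grafts split between the two
    libraries; the remainder are random singleton fillers. A fixed count
    round(duplicate_fraction * n_first_library) of first-library
    compounds is copied into the second library under new plate/well
    positions. Deterministic under cfg.seed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_class = [np.random.default_rng(s) for s in ss.spawn(2)]

    prefixes = ("T", "S")
    per_lib_smiles: list[list[tuple[str, str, str]]] = [[], []]  # (name, smiles, family)
    seen: set[str] = set()

    for fam_name, core, subs in cfg.scaffold_families:
        order = list(rng_struct.permutation(len(subs)))
        half = len(order) // 2
        for lib_idx, idxs in enumerate((order[:half], order[half:])):
            for k in idxs:
                smi = core.replace("{R}", subs[k])
                mol = Chem.MolFromSmiles(smi)
                if mol is None:  # bad graft: skip, logged by rdkit silence
                    continue
                canon = Chem.MolToSmiles(mol)
                if canon in seen:
                    continue
                seen.add(canon)
                per_lib_smiles[lib_idx].append(
                    (f"{fam_name}-{subs[k]}", canon, fam_name)
                )

    n_dup = int(round(cfg.duplicate_fraction * cfg.n_compounds[0]))
    targets = [cfg.n_compounds[0], cfg.n_compounds[1] - n_dup]
    for lib_idx in (0, 1):
        filler_no = 0
        while len(per_lib_smiles[lib_idx]) < targets[lib_idx]:
            smi = _filler_smiles(rng_struct)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            filler_no += 1
            per_lib_smiles[lib_idx].append(
                (f"filler-{prefixes[lib_idx]}{filler_no}", canon, "")
            )

    compounds: list[Compound] = []
    class_of: dict[str, str] = {}
    family_of: dict[str, str] = {}
    family_class = {
        fam: _draw(rng_class, cfg.family_class_weights)
        for fam, _, _ in cfg.scaffold_families
    }

    positions = [_wells(p) for p in prefixes]
    counters = [0, 0]

    def add(lib_idx: int, name: str, smiles: str, fam: str, cls: str) -> Compound:
        counters[lib_idx] += 1
        cid = f"{prefixes[lib_idx]}{counters[lib_idx]:05d}"
        plate, well = next(positions[lib_idx])
        c = make_compound(cid, prefixes[lib_idx], plate, well, name, smiles)
        compounds.append(c)
        class_of[cid] = cls
        family_of[cid] = fam
        return c

    lib_first: list[Compound] = []
    for lib_idx in (0, 1):
        for name, smiles, fam in per_lib_smiles[lib_idx]:
            if fam and rng_class.random() < cfg.sar_coherence:
                cls = family_class[fam]
            else:
                cls = _draw(rng_class, cfg.class_proportions)
            c = add(lib_idx, name, smiles, fam, cls)
            if lib_idx == 0:
                lib_first.append(c)

    dup_pairs: list[tuple[str, str]] = []
    dup_sources = rng_struct.choice(len(lib_first), size=n_dup, replace=False)
    for i in sorted(int(x) for x in dup_sources):
        src = lib_first[i]
        copy = add(1, src.name, src.smiles, family_of[src.compound_id],
                   class_of[src.compound_id])
        dup_pairs.append((src.compound_id, copy.compound_id))

    return compounds, GroundTruth(class_of, family_of, sorted(dup_pairs))


def _score_probs(base: int, noise: float) -> np.ndarray:
    """Categorical distribution over scores 0-3: mass `noise` split to the
    adjacent scores (mass at an invalid neighbour stays on the base)."""
    p = np.zeros(4)
    p[base] = 1.0 - noise
    for nb in (base - 1, base + 1):
        if 0 <= nb <= 3:
            p[nb] += noise / 2.0
        else:
            p[base] += noise / 2.0
    return p


def _simulate_well(
    cid: str, assay: Assay, cls: str, cfg: SynthConfig, rng: np.random.Generator
) -> WellResult:
    probs = _score_probs(BASE_SCORES[cls][assay], cfg.score_noise)
    dp = cfg.death_prob.get(cls, 0.0)
    n_dead = int(rng.binomial(3, dp))
    scores = [int(rng.choice(4, p=probs)) for _ in range(3 - n_dead)]
    return WellResult(
        compound_id=cid,
        assay=assay,
        embryo_scores=scores,
        n_embryos_found=3,
        n_dead_or_abnormal=n_dead,
    )


def simulate_screen(
    lib: list[Compound], truth: GroundTruth, cfg: SynthConfig
) -> list[WellResult]:
    """Simulate the full cascade of wells for a generated library.

    Every compound gets a primary weak-allele well; compounds whose
    primary category is A-C get two retest wells; compounds passing the
    hit rule get two counter-screen wells; counter-screen rescuers get
    one strong-allele well. Scores are drawn per embryo from the
    class/assay categorical distribution; deaths are Bernoulli per
    embryo. Deterministic under cfg.seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    wells: list[WellResult] = []
    for c in lib:
        cls = truth.class_of[c.compound_id]
        primary = _simulate_well(c.compound_id, Assay.VCANB_TB233C, cls, cfg, rng)
        wells.append(primary)
        ps = tri.score_well(primary)
        if tri.categorize_primary(ps) not in (Category.A, Category.B, Category.C):
            continue
        retests = [
            _simulate_well(c.compound_id, Assay.VCANB_TB233C, cls, cfg, rng)
            for _ in range(2)
        ]
        wells.extend(retests)
        rs = [tri.score_well(w) for w in retests]
        if any(s.outcome is not tri.WellOutcome.SCORED for s in rs):
            continue
        _, is_hit, _ = tri.select_hits(ps.total, [s.total for s in rs])
        if not is_hit:
            continue
        mbp = [
            _simulate_well(c.compound_id, Assay.MBP_TB233C, cls, cfg, rng)
            for _ in range(2)
        ]
        wells.extend(mbp)
        ms = [tri.score_well(w) for w in mbp]
        totals = [s.total for s in ms if s.outcome is tri.WellOutcome.SCORED]
        if not totals:
            continue
        if tri.classify_mbp(sum(totals) / len(totals)) is MbpClass.RESCUE:
            wells.append(
                _simulate_well(c.compound_id, Assay.VCANB_FR24, cls, cfg, rng)
            )
    return wells


def expected_outcome(cls: str) -> dict:
    """Pipeline outcome implied by a planted class under noise-free scoring."""
    return {
        "downstream_agonist": dict(is_hit=True, mbp_class=MbpClass.RESCUE,
                                   mechanism=MechanismClass.DOWNSTREAM),
        "receptor_agonist": dict(is_hit=True, mbp_class=MbpClass.RESCUE,
                                 mechanism=MechanismClass.RECEPTOR_CANDIDATE),
        "ear_specific": dict(is_hit=True, mbp_class=MbpClass.NO_RESCUE,
                             mechanism=None),
        "transcription_inhibitor": dict(is_hit=True,
                                        mbp_class=MbpClass.DOWNREGULATED,
                                        mechanism=None),
        "inactive": dict(is_hit=False, mbp_class=None, mechanism=None),
        "toxic": dict(is_hit=False, mbp_class=None, mechanism=None),
    }[cls]


def evaluate_recovery(truth: GroundTruth, records: list[TriageRecord]) -> dict:
    """Score pipeline output against the planted ground truth.

    Returns hit recall/precision per planted class, the mechanism-class
    confusion matrix for planted agonists, and overall outcome accuracy
    over non-toxic compounds.
    """
    by_id = {r.compound_id: r for r in records}
    missing = set(truth.class_of) - set(by_id)
    if missing:
        raise ValueError(f"{len(missing)} compounds lack triage records")

    recall: dict[str, float] = {}
    per_class_n: dict[str, int] = {}
    for cls in CLASSES:
        ids = [cid for cid, c in truth.class_of.items() if c == cls]
        per_class_n[cls] = len(ids)
        if not ids:
            continue
        want_hit = expected_outcome(cls)["is_hit"]
        agree = sum(1 for cid in ids if by_id[cid].is_hit == want_hit)
        recall[cls] = agree / len(ids)

    hits = [r for r in records if r.is_hit]
    true_active = {
        cid for cid, c in truth.class_of.items() if expected_outcome(c)["is_hit"]
    }
    precision = (
        sum(1 for r in hits if r.compound_id in true_active) / len(hits)
        if hits else float("nan")
    )

    confusion: dict[tuple[str, str], int] = {}
    n_correct = 0
    n_scored = 0
    for cid, cls in truth.class_of.items():
        if cls == "toxic":
            continue
        exp = expected_outcome(cls)
        rec = by_id[cid]
        n_scored += 1
        ok = rec.is_hit == exp["is_hit"]
        if exp["is_hit"]:
            ok = ok and rec.mbp_class == exp["mbp_class"]
        if exp["mechanism"] is not None:
            key = (cls, rec.mechanism_class.value if rec.mechanism_class else "none")
            confusion[key] = confusion.get(key, 0) + 1
            ok = ok and rec.mechanism_class == exp["mechanism"]
        if ok:
            n_correct += 1
    return {
        "hit_recall": recall,
        "hit_precision": precision,
        "n_per_class": per_class_n,
        "mechanism_confusion": confusion,
        "outcome_accuracy_nontoxic": n_correct / n_scored if n_scored else float("nan"),
    }
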