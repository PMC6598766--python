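"""File formats, plate maps and run configuration.

All tabular interchange is UTF-8 CSV with a header; networks export to
GraphML and SIF; configuration loads from YAML/JSON and is hashed into
output metadata so any result can be traced to the rules that produced
it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .chem import Compound, make_compound
from .layout import SimilarityNetwork
from .triage import (
    DEFAULT_CATEGORY_BINS,
    Category,
    MbpClass,
    MechanismClass,
    TriageRecord,
    WellResult,
    validate_category_bins,
)

CONTROL_ROLES = {
    "positive_control_IBMX_50",
    "positive_control_IBMX_100",
    "negative_control_DMSO",
    "untreated_wt",
}
ROLES = CONTROL_ROLES | {"compound"}


class SchemaError(ValueError):
    """A file violated its schema; names file, row and column."""

    def __init__(self, path, row, column, message):
        super().__init__(f"{path}:row {row}:{column}: {message}")


@dataclass
class PlateMap:
    """Role of each well on a plate; columns 1 and 12 are controls only."""

    plate_id: str
    roles: dict[str, str]  # well -> role

    def __post_init__(self):
        for well, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for well {well}")
            col = int(well[1:])
            if col in (1, 12) and role == "compound":
                raise ValueError(
                    f"well {well}: columns 1 and 12 are reserved for controls"
                )
            if col not in (1, 12) and role != "compound":
                raise ValueError(f"well {well}: control role outside columns 1/12")


def default_plate_map(plate_id: str) -> PlateMap:
    """The screening layout: compounds in columns 2-11; IBMX 50/100 uM,
    1% DMSO and untreated wild-type controls alternating in columns 1/12."""
    roles = {}
    control_cycle = [
        "positive_control_IBMX_50",
        "positive_control_IBMX_100",
        "negative_control_DMSO",
        "untreated_wt",
    ]
    for i, row in enumerate("ABCDEFGH"):
        roles[f"{row}01"] = control_cycle[i % 4]
        roles[f"{row}12"] = control_cycle[(i + 2) % 4]
        for col in range(2, 12):
            roles[f"{row}{col:02d}"] = "compound"
    return PlateMap(plate_id, roles)


@dataclass
class RunConfig:
    """Tunable decision rules, serialised into every output's metadata."""

    category_bins: dict[Category, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_BINS)
    )
    mbp_rescue_min: float = 3.5
    mbp_downregulated_max: float = 1.5
    fr24_downstream_max: float = 7.0
    fr24_receptor_min: float = 9.0
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048
    network_threshold: float = 0.5
    jitter_seed: int = 0
    toxicity_rule: str = "any"

    def __post_init__(self):
        validate_category_bins(self.category_bins)
        if not 0 <= self.network_threshold <= 1:
            raise ValueError("network threshold outside [0, 1]")
        if self.toxicity_rule not in ("any", "majority"):
            raise ValueError("toxicity_rule must be 'any' or 'majority'")

    def to_dict(self) -> dict:
        return {
            "category_bins": {c.value: list(v) for c, v in self.category_bins.items()},
            "mbp_rescue_min": self.mbp_rescue_min,
            "mbp_downregulated_max": self.mbp_downregulated_max,
            "fr24_downstream_max": self.fr24_downstream_max,
            "fr24_receptor_min": self.fr24_receptor_min,
            "fingerprint_radius": self.fingerprint_radius,
            "fingerprint_bits": self.fingerprint_bits,
            "network_threshold": self.network_threshold,
            "jitter_seed": self.jitter_seed,
            "toxicity_rule": self.toxicity_rule,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "category_bins" in raw:
            raw["category_bins"] = {
                Category(k): tuple(v) for k, v in raw["category_bins"].items()
            }
        return cls(**raw)


def read_library(path) -> list[Compound]:
    """Load a compound library CSV (library_id, plate, well, name, smiles).

    An optional compound_id column is honoured; otherwise ids are
    library_id + row number. Structures are standardised and identity
    keys computed on load.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"library_id", "plate", "well", "name", "smiles"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(path, 0, ",".join(sorted(missing)), "missing column(s)")
    out = []
    for i, row in df.iterrows():
        cid = row.get("compound_id") or f"{row['library_id']}{i + 1:05d}"
        try:
            out.append(
                make_compound(
                    cid, row["library_id"], row["plate"], row["well"],
                    row["name"], row["smiles"],
                )
            )
        except (ValueError, TypeError) as e:
            raise SchemaError(path, i + 2, "well/smiles", str(e)) from e
    return out


def write_library(compounds: list[Compound], path) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": c.compound_id,
                "library_id": c.library_id,
                "plate": c.plate,
                "well": c.well,
                "name": c.name,
                "smiles": c.smiles,
                "identity_key": c.identity_key or "",
            }
            for c in compounds
        ]
    ).to_csv(path, index=False)


def read_wells(path, plate_map: dict[str, PlateMap] | None = None) -> list[WellResult]:
    """Load well results CSV.

    Columns: compound_id, assay, concentration, embryo_scores
    (semicolon-separated), n_found, n_dead; optional plate/well for
    plate-map validation (a compound entry in a control column is a
    schema error).
    """
    df = pd.read_csv(path, dtype=str)
    required = {"compound_id", "assay", "embryo_scores", "n_found", "n_dead"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(path, 0, ",".join(sorted(missing)), "missing column(s)")
    out = []
    for i, row in df.iterrows():
        if plate_map is not None and "plate" in df.columns and "well" in df.columns:
            pm = plate_map.get(row["plate"])
            if pm is not None and pm.roles.get(row["well"]) != "compound":
                raise SchemaError(
                    path, i + 2, "well",
                    f"well {row['well']} on {row['plate']} is not a compound well",
                )
        raw = str(row["embryo_scores"]).strip()
        scores = [int(s) for s in raw.split(";") if s != ""] if raw not in ("", "nan") else []
        try:
            out.append(
                WellResult(
                    compound_id=row["compound_id"],
                    assay=row["assay"],
                    embryo_scores=scores,
                    n_embryos_found=int(row["n_found"]),
                    n_dead_or_abnormal=int(row["n_dead"]),
                    concentration=float(row.get("concentration", 25.0) or 25.0),
                )
            )
        except ValueError as e:
            raise SchemaError(path, i + 2, "embryo_scores", str(e)) from e
    return out


def write_wells(wells: list[WellResult], path) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": w.compound_id,
                "assay": w.assay.value,
                "concentration": w.concentration,
                "embryo_scores": ";".join(str(s) for s in w.embryo_scores),
                "n_found": w.n_embryos_found,
                "n_dead": w.n_dead_or_abnormal,
            }
            for w in wells
        ]
    ).to_csv(path, index=False)


_TRIAGE_COLUMNS = [
    "compound_id", "plate", "well", "name", "primary_sum", "primary_category",
    "retest_sums", "vcanb_average", "is_hit", "incomplete", "mbp_average",
    "mbp_class", "fr24_sum", "mechanism_class",
]


def write_triage(records: list[TriageRecord], path, config: RunConfig | None = None) -> None:
    """Write triage records as CSV; averages rounded to two decimals at
    reporting only. A config hash comment line precedes the header."""
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "plate": r.plate,
                "well": r.well,
                "name": r.name,
                "primary_sum": "" if r.primary_sum is None else r.primary_sum,
                "primary_category": r.primary_category.value if r.primary_category else "",
                "retest_sums": ";".join(str(s) for s in r.retest_sums),
                "vcanb_average": "" if r.vcanb_average is None else f"{r.vcanb_average:.2f}",
                "is_hit": int(r.is_hit),
                "incomplete": int(r.incomplete),
                "mbp_average": "" if r.mbp_average is None else f"{r.mbp_average:.2f}",
                "mbp_class": r.mbp_class.value if r.mbp_class else "",
                "fr24_sum": "" if r.fr24_sum is None else (
                    r.fr24_sum if isinstance(r.fr24_sum, str) else f"{r.fr24_sum:.2f}"
                ),
                "mechanism_class": r.mechanism_class.value if r.mechanism_class else "",
            }
        )
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.config_hash()}\n")
        pd.DataFrame(rows, columns=_TRIAGE_COLUMNS).to_csv(fh, index=False)


def read_triage(path) -> list[TriageRecord]:
    # only whole leading lines are comments; '#' is legal inside names
    # (SMILES-derived names can contain it), so pandas' comment= is unsafe
    import io as _io

    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines(keepends=True)
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        start += 1
    df = pd.read_csv(_io.StringIO("".join(lines[start:])), dtype=str)
    out = []
    for _, row in df.iterrows():
        def _s(key):
            v = row.get(key)
            return None if v is None or pd.isna(v) or v == "" else v

        fr24 = _s("fr24_sum")
        if fr24 is not None and fr24 not in ("ND", "DE"):
            fr24 = float(fr24)
        out.append(
            TriageRecord(
                compound_id=row["compound_id"],
                plate=_s("plate") or "",
                well=_s("well") or "",
                name=_s("name") or "",
                primary_sum=None if _s("primary_sum") is None else int(row["primary_sum"]),
                primary_category=None if _s("primary_category") is None
                else Category(row["primary_category"]),
                retest_sums=[int(s) for s in str(_s("retest_sums") or "").split(";") if s],
                vcanb_average=None if _s("vcanb_average") is None else float(row["vcanb_average"]),
                is_hit=bool(int(row["is_hit"])),
                incomplete=bool(int(row["incomplete"])),
                mbp_average=None if _s("mbp_average") is None else float(row["mbp_average"]),
                mbp_class=None if _s("mbp_class") is None else MbpClass(row["mbp_class"]),
                fr24_sum=fr24,
                mechanism_class=None if _s("mechanism_class") is None
                else MechanismClass(row["mechanism_class"]),
            )
        )
    return out


def export_network(net: SimilarityNetwork, path, fmt: str = "graphml") -> None:
    """Write the similarity network as GraphML or SIF (Cytoscape-ready)."""
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph()
        for n, attrs in net.graph.nodes(data=True):
            g.add_node(n, **{k: str(v) for k, v in attrs.items()})
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, weight=float(d.get("weight", 1.0)))
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            isolated = set(net.graph.nodes)
            for u, v in net.graph.edges:
                fh.write(f"{u}\tsim\t{v}\n")
                isolated.discard(u)
                isolated.discard(v)
            for n in sorted(isolated):
                fh.write(f"{n}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def load_hit_table() -> pd.DataFrame:
    """Bundled table of the 41 confirmed screen hits.

    Columns: row, plate, well, name, vcanb_score (nine-embryo average),
    mbp_score (six-embryo average), fr24_score (three-embryo strong-
    allele sum, or ND/DE for missing data / dead embryos).
    """
    with resources.files("zfscreen.data").joinpath("hit_table.csv").open() as fh:
        return pd.read_csv(fh, dtype={"fr24_score": str})


def hit_table_records() -> list[TriageRecord]:
    """The bundled 41-hit table as TriageRecords ready for classification."""
    from .triage import classify_fr24, classify_mbp

    df = load_hit_table()
    out = []
    for _, row in df.iterrows():
        fr24 = row["fr24_score"]
        if fr24 not in ("ND", "DE"):
            fr24 = float(fr24)
        rec = TriageRecord(
            compound_id=f"{row['plate']}-{row['well']}",
            plate=row["plate"],
            well=row["well"],
            name=row["name"],
            vcanb_average=float(row["vcanb_score"]),
            is_hit=True,
            mbp_average=float(row["mbp_score"]),
            fr24_sum=fr24,
        )
        rec.mbp_class = classify_mbp(rec.mbp_average)
        rec.mechanism_class = classify_fr24(rec.fr24_sum)
        out.append(rec)
    return out
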