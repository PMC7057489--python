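"""Readers and writers for the model's external file formats.

Input layers:

* ``centres.csv`` — one row per population centre with coordinates,
  population, demographic proportions, family-physician count, seven
  deprivation-index indicator columns (``vx_1`` .. ``vx_7``) and five
  yes/no readiness columns (``fp_adequate_override`` optional).
* ``blocks.geojson`` (Point features) or ``blocks.csv`` — population
  blocks: ``block_id``, coordinates, ``population``.
* ``network.geojson`` — LineString features with ``length_km`` and
  ``speed_kmh`` properties; shared endpoints (within 1 mm) become
  shared graph nodes.
* ``facilities.csv`` — ``facility_id``, ``name``, coordinates, ``kind``
  (hospital/hospice), ``beds``.

All coordinates must already be in one planar metric coordinate system
(metres); this package performs no reprojection.  Output is
``ranking.csv``, one row per scored community in rank order.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import List, Optional, Sequence, Union

import pandas as pd

from .model import (
    Dataset,
    Facility,
    PopulationBlock,
    PopulationCentre,
    ReadinessFlags,
    SSMResult,
    ValidationError,
    parse_yes_no,
)
from .network import RoadNetwork, build_graph
from .aggregate import round_display

__all__ = ["read_dataset", "read_centres", "read_blocks", "read_network",
           "read_facilities", "write_ranking", "write_dataset"]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

VANDIX_COLUMNS = [f"vx_{i}" for i in range(1, 8)]
READINESS_COLUMNS = ["aware", "education", "telemedicine", "momentum"]

_CENTRE_REQUIRED = [
    "community_id", "name", "x", "y", "population",
    "pct_over75", "pct_female", "pct_alone", "fp_count",
] + VANDIX_COLUMNS


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {', '.join(missing)}")


def read_centres(path: PathLike) -> List[PopulationCentre]:
    df = pd.read_csv(path, dtype={"community_id": str})
    _require_columns(df, _CENTRE_REQUIRED, path)
    for col in READINESS_COLUMNS:
        if col not in df.columns:
            logger.warning(
                "%s: readiness column %r absent; defaulting to 'no' for all "
                "communities", path, col
            )
    has_override = "fp_adequate_override" in df.columns
    centres = []
    for _, row in df.iterrows():
        flags = {}
        for col in READINESS_COLUMNS:
            if col in df.columns and not _is_missing(row[col]):
                flags[col] = parse_yes_no(row[col], f"{path}:{col}")
            else:
                flags[col] = False
        fp_override: Optional[bool] = None
        if has_override and not _is_missing(row["fp_adequate_override"]):
            fp_override = parse_yes_no(
                row["fp_adequate_override"], f"{path}:fp_adequate_override"
            )
        centres.append(
            PopulationCentre(
                community_id=str(row["community_id"]),
                name=str(row["name"]),
                location=(float(row["x"]), float(row["y"])),
                population=float(row["population"]),
                pct_over75=float(row["pct_over75"]),
                pct_female=float(row["pct_female"]),
                pct_alone=float(row["pct_alone"]),
                fp_count=int(row["fp_count"]),
                vandix_indicators=tuple(float(row[c]) for c in VANDIX_COLUMNS),
                readiness=ReadinessFlags(
                    aware=flags["aware"],
                    education=flags["education"],
                    telemedicine=flags["telemedicine"],
                    fp_adequate=fp_override,
                    momentum=flags["momentum"],
                ),
            )
        )
    return centres


def _is_missing(value: object) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def read_blocks(path: PathLike) -> List[PopulationBlock]:
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        doc = json.loads(path.read_text())
        blocks = []
        for feat in doc.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ValidationError(f"{path}: blocks must be Point features")
            props = feat.get("properties") or {}
            if "block_id" not in props or "population" not in props:
                raise ValidationError(
                    f"{path}: block features need block_id and population properties"
                )
            x, y = geom["coordinates"][:2]
            blocks.append(
                PopulationBlock(
                    block_id=str(props["block_id"]),
                    location=(float(x), float(y)),
                    population=float(props["population"]),
                )
            )
        return blocks
    df = pd.read_csv(path, dtype={"block_id": str})
    _require_columns(df, ["block_id", "x", "y", "population"], path)
    return [
        PopulationBlock(
            block_id=str(r["block_id"]),
            location=(float(r["x"]), float(r["y"])),
            population=float(r["population"]),
        )
        for _, r in df.iterrows()
    ]


def read_network(path: PathLike) -> RoadNetwork:
    doc = json.loads(Path(path).read_text())
    features = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise ValidationError(
                f"{path}: feature {i}: road features must be LineStrings, "
                f"got {geom.get('type')!r}"
            )
        props = feat.get("properties") or {}
        for key in ("length_km", "speed_kmh"):
            if key not in props:
                raise ValidationError(f"{path}: feature {i}: missing property {key!r}")
        features.append(
            {
                "coords": [tuple(map(float, pt[:2])) for pt in geom["coordinates"]],
                "length_km": props["length_km"],
                "speed_kmh": props["speed_kmh"],
            }
        )
    return build_graph(features)


def read_facilities(path: PathLike) -> List[Facility]:
    df = pd.read_csv(path, dtype={"facility_id": str})
    _require_columns(df, ["facility_id", "name", "x", "y", "kind", "beds"], path)
    return [
        Facility(
            facility_id=str(r["facility_id"]),
            name=str(r["name"]),
            location=(float(r["x"]), float(r["y"])),
            kind=str(r["kind"]).strip().lower(),
            beds=int(r["beds"]),
        )
        for _, r in df.iterrows()
    ]


def read_dataset(
    centres_path: PathLike,
    blocks_path: PathLike,
    network_path: PathLike,
    facilities_path: PathLike,
) -> Dataset:
    """Read the four input layers and assemble a validated Dataset."""
    return Dataset(
        centres=read_centres(centres_path),
        blocks=read_blocks(blocks_path),
        network=read_network(network_path),
        facilities=read_facilities(facilities_path),
    )


RANKING_COLUMNS = [
    "community_id", "name", "population_score", "isolation_score",
    "vulnerability_score", "readiness_score", "ssm_score", "eligible", "rank",
]


def write_ranking(
    results: Sequence[SSMResult], path: PathLike, display_decimals: int = 2
) -> None:
    """Serialize ranked results to CSV, scores at display precision."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RANKING_COLUMNS)
        for r in results:
            c = r.components
            writer.writerow(
                [
                    r.community_id,
                    r.name,
                    round_display(c.population, display_decimals),
                    round_display(c.isolation, display_decimals),
                    round_display(c.vulnerability, display_decimals),
                    round_display(c.readiness, display_decimals),
                    round_display(r.ssm_score, display_decimals),
                    str(bool(r.eligible)).lower(),
                    r.rank,
                ]
            )


# ---------------------------------------------------------------------------
# writers for the input layers (used by the synthetic-region generator)

def _fmt(x: float) -> str:
    return repr(float(x))


def write_dataset(dataset: Dataset, out_dir: PathLike) -> dict:
    """Write a Dataset as the standard input file set.

    Returns a mapping layer-name -> written path.  Round-trips through
    :func:`read_dataset` up to float representation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "centres": out / "centres.csv",
        "blocks": out / "blocks.geojson",
        "network": out / "network.geojson",
        "facilities": out / "facilities.csv",
    }

    with open(paths["centres"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            _CENTRE_REQUIRED + READINESS_COLUMNS + ["fp_adequate_override"]
        )
        for c in dataset.centres:
            fl = c.readiness
            writer.writerow(
                [
                    c.community_id, c.name, _fmt(c.location[0]), _fmt(c.location[1]),
                    _fmt(c.population), _fmt(c.pct_over75), _fmt(c.pct_female),
                    _fmt(c.pct_alone), c.fp_count,
                ]
                + [_fmt(v) for v in c.vandix_indicators]
                + [
                    "yes" if fl.aware else "no",
                    "yes" if fl.education else "no",
                    "yes" if fl.telemedicine else "no",
                    "yes" if fl.momentum else "no",
                    "" if fl.fp_adequate is None else ("yes" if fl.fp_adequate else "no"),
                ]
            )

    blocks_doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(b.location)},
                "properties": {"block_id": b.block_id, "population": b.population},
            }
            for b in dataset.blocks
        ],
    }
    paths["blocks"].write_text(json.dumps(blocks_doc, sort_keys=True, indent=1))

    net = dataset.network
    features = []
    for a, b, minutes in net.edges:
        pa, pb = net.nodes[a], net.nodes[b]
        # serialize at 60 km/h so length alone carries the travel time
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": [list(pa), list(pb)]},
                "properties": {"length_km": minutes, "speed_kmh": 60.0},
            }
        )
    net_doc = {"type": "FeatureCollection", "features": features}
    paths["network"].write_text(json.dumps(net_doc, sort_keys=True, indent=1))

    with open(paths["facilities"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["facility_id", "name", "x", "y", "kind", "beds"])
        for f in dataset.facilities:
            writer.writerow(
                [f.facility_id, f.name, _fmt(f.location[0]), _fmt(f.location[1]),
                 f.kind, f.beds]
            )

    return {k: str(v) for k, v in paths.items()}
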