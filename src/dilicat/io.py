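"""Reading and writing case tables, phenotype files, and score reports.

Case tables are UTF-8 CSV with a header row and either pre-derived
features (``case_id, drug, latency_days, r_value, ast_alt_ratio``) or
raw onset labs (``case_id, drug, latency_days, alt, alt_uln, alp,
alp_uln, ast``), from which the features are derived at ingest.

Phenotype files are JSON with a mandatory schema version.  All outputs
embed tool version, configuration hash, and seed (reproducibility
contract); in CSV these are ``#``-prefixed header comments.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import __version__
from .phenotype import (
    FEATURES,
    KNOT_NAMES,
    CaseRecord,
    DrugPhenotype,
    FeaturePhenotype,
    PhenotypeConfig,
    RawLabs,
    ValidationError,
    derive_features,
)
from .scoring import CaseScore, CohortSummary

__all__ = [
    "SCHEMA_VERSION",
    "read_cases",
    "write_cases",
    "read_phenotype",
    "write_phenotype",
    "write_score_report",
    "read_score_report",
    "config_hash",
]

SCHEMA_VERSION = "1.0"

_RATIO_COLS = ["case_id", "drug", "latency_days", "r_value", "ast_alt_ratio"]
_RAW_COLS = ["case_id", "drug", "latency_days", "alt", "alt_uln", "alp",
             "alp_uln", "ast"]


def config_hash(config: Any) -> str:
    """Short stable hash of a configuration dataclass (or mapping)."""
    try:
        payload = asdict(config)
    except TypeError:
        payload = dict(config) if config is not None else {}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _metadata_lines(config: Any = None, seed: int | None = None) -> list[str]:
    lines = [f"# dilicat_version={__version__}",
             f"# config_hash={config_hash(config)}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


def read_cases(path: str | Path,
               config: PhenotypeConfig | None = None) -> list[CaseRecord]:
    """Read a case CSV, deriving features from raw labs if needed.

    Malformed rows raise a validation error naming the offending row.
    """
    config = config or PhenotypeConfig()
    try:
        df = pd.read_csv(path, comment="#", dtype={"case_id": str, "drug": str},
                         float_precision="round_trip")
    except Exception as exc:  # unreadable / unparseable file
        raise ValidationError(f"cannot read case table {path}: {exc}") from exc
    cols = list(df.columns)
    if all(c in cols for c in _RATIO_COLS):
        raw = False
    elif all(c in cols for c in _RAW_COLS):
        raw = True
    else:
        raise ValidationError(
            f"case table {path} must have columns {_RATIO_COLS} or {_RAW_COLS}; "
            f"found {cols}")
    if df.empty:
        raise ValidationError(f"case table {path} contains no cases")
    cases: list[CaseRecord] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        try:
            if raw:
                labs = RawLabs(alt=float(row["alt"]), alt_uln=float(row["alt_uln"]),
                               alp=float(row["alp"]), alp_uln=float(row["alp_uln"]),
                               ast=float(row["ast"]))
                case = derive_features(labs, float(row["latency_days"]),
                                       case_id=str(row["case_id"]),
                                       drug=str(row["drug"]), config=config)
            else:
                latency = float(row["latency_days"])
                if config.round_latency:
                    latency = float(round(latency))
                case = CaseRecord(case_id=str(row["case_id"]),
                                  drug=str(row["drug"]),
                                  latency_days=latency,
                                  r_value=float(row["r_value"]),
                                  ast_alt_ratio=float(row["ast_alt_ratio"]))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, row {rowno}: {exc}") from exc
        cases.append(case)
    return cases


def write_cases(path: str | Path, cases: Sequence[CaseRecord],
                config: Any = None, seed: int | None = None) -> None:
    """Write cases in the pre-derived-feature CSV schema."""
    df = pd.DataFrame([
        {"case_id": c.case_id, "drug": c.drug, "latency_days": c.latency_days,
         "r_value": c.r_value, "ast_alt_ratio": c.ast_alt_ratio}
        for c in cases
    ], columns=_RATIO_COLS)
    with open(path, "w", encoding="utf-8") as fh:
        for line in _metadata_lines(config, seed):
            fh.write(line + "\n")
        # %.17g keeps float64 values bit-exact through a CSV round-trip
        df.to_csv(fh, index=False, float_format="%.17g")


def _fence_out(v: float) -> float | None:
    return None if math.isinf(v) else float(v)


def _fence_in(v: float | None, sign: int) -> float:
    return sign * math.inf if v is None else float(v)


def write_phenotype(path: str | Path, phenotype: DrugPhenotype,
                    config: Any = None, seed: int | None = None) -> None:
    """Write a drug phenotype as JSON (schema version mandatory)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "dilicat_version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "drug": phenotype.drug,
        "n_cases": phenotype.n_cases,
        "provenance": phenotype.provenance,
        "features": {},
    }
    for f in FEATURES:
        fp = phenotype.feature_phenotype(f)
        doc["features"][f] = {
            "knots": dict(zip(KNOT_NAMES, fp.knots)),
            "lower_fence": _fence_out(fp.lower_fence),
            "upper_fence": _fence_out(fp.upper_fence),
            "n": fp.n,
            "interpolated_knots": list(fp.interpolated_knots),
            "notes": fp.notes,
        }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_phenotype(path: str | Path) -> DrugPhenotype:
    """Parse a phenotype JSON file back into a :class:`DrugPhenotype`."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except Exception as exc:
        raise ValidationError(f"cannot read phenotype file {path}: {exc}") from exc
    if "schema_version" not in doc:
        raise ValidationError(f"phenotype file {path} lacks a schema_version")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ValidationError(
            f"phenotype file {path}: unsupported schema_version "
            f"{doc['schema_version']!r} (expected {SCHEMA_VERSION!r})")
    feats = {}
    for f in FEATURES:
        try:
            fd = doc["features"][f]
            feats[f] = FeaturePhenotype(
                feature=f,
                knots=tuple(fd["knots"][k] for k in KNOT_NAMES),
                lower_fence=_fence_in(fd["lower_fence"], -1),
                upper_fence=_fence_in(fd["upper_fence"], +1),
                n=int(fd["n"]),
                interpolated_knots=tuple(fd.get("interpolated_knots", ())),
                notes=fd.get("notes", ""))
        except (KeyError, TypeError) as exc:
            raise ValidationError(
                f"phenotype file {path}: malformed feature {f!r}: {exc}") from exc
    return DrugPhenotype(drug=doc["drug"], latency=feats["latency"],
                         r_value=feats["r_value"],
                         ast_alt_ratio=feats["ast_alt_ratio"],
                         n_cases=int(doc["n_cases"]),
                         provenance=doc.get("provenance", ""))


def write_score_report(path: str | Path, scores: Sequence[CaseScore],
                       summary: CohortSummary, config: Any = None,
                       seed: int | None = None) -> None:
    """Write per-case scores plus cohort medians as JSON."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "dilicat_version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "weighted_feature": summary.weighted_feature,
        "cases": [
            {"case_id": s.case_id,
             "subscores": s.subscores,
             "bands": s.bands,
             "weighted_feature": s.weighted_feature,
             "unweighted_total": s.unweighted_total,
             "weighted_total": s.weighted_total}
            for s in scores
        ],
        "summary": {
            "n": summary.n,
            "median_subscores": summary.median_subscores,
            "median_unweighted": summary.median_unweighted,
            "median_weighted": summary.median_weighted,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_score_report(path: str | Path) -> tuple[list[CaseScore], CohortSummary]:
    """Parse a score report back into scores + summary (round-trip)."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    scores = [
        CaseScore(case_id=c["case_id"],
                  subscores={f: int(c["subscores"][f]) for f in FEATURES},
                  bands={f: c["bands"][f] for f in FEATURES},
                  weighted_feature=c["weighted_feature"],
                  unweighted_total=int(c["unweighted_total"]),
                  weighted_total=int(c["weighted_total"]))
        for c in doc["cases"]
    ]
    s = doc["summary"]
    summary = CohortSummary(n=int(s["n"]),
                            median_subscores={f: float(s["median_subscores"][f])
                                              for f in FEATURES},
                            median_unweighted=float(s["median_unweighted"]),
                            median_weighted=float(s["median_weighted"]),
                            weighted_feature=doc["weighted_feature"])
    return scores, summary
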