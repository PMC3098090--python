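"""Placement file format and run management (merge / split / filter).

Runs are serialized as structured JSON modeled on the community ``jplace``
specification: the reference tree with ``{edge number}`` annotations, an
ordered ``fields`` schema, and one candidate row per (query, edge).  A
digest of the canonicalized reference tree plus model text travels with
every file so that shards from different references cannot be merged by
accident.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field

from .confidence import QueryPlacement
from .placement import PlacementCandidate
from .reference import parse_newick

__all__ = [
    "PlacementRun",
    "FORMAT_VERSION",
    "canonical_newick",
    "run_checksum",
    "write_place",
    "read_place",
    "merge",
    "split",
    "filter_run",
]

FORMAT_VERSION = "1"

CORE_FIELDS = ["edge_num", "likelihood", "like_weight_ratio",
               "distal_length", "pendant_length"]
OPT_FIELDS = ["marginal_like", "post_prob"]

_FIELD_ATTR = {
    "edge_num": "edge",
    "likelihood": "log_like",
    "like_weight_ratio": "lwr",
    "distal_length": "attach_a",
    "pendant_length": "pendant_b",
    "marginal_like": "log_marginal",
    "post_prob": "posterior",
}


def canonical_newick(newick: str) -> str:
    """Canonical form of a reference tree for checksumming: deterministic
    root and child order, fixed precision, edge numbers stripped."""
    stripped = re.sub(r"\{\d+\}", "", newick)
    return parse_newick(stripped).newick(edge_numbers=False, fmt="%.6g")


def run_checksum(tree_newick: str, model_text: str) -> str:
    canon_model = "\n".join(l.strip() for l in model_text.strip().splitlines()
                            if l.strip())
    payload = canonical_newick(tree_newick) + "\n" + canon_model
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class PlacementRun:
    """A placement file in memory: reference tree, model, and placements."""

    reference_tree: str                 # edge-numbered newick
    model_text: str
    placements: list = field(default_factory=list)
    fields: list = None
    format_version: str = FORMAT_VERSION

    def __post_init__(self):
        if self.fields is None:
            self.fields = list(CORE_FIELDS)
            if any(c.posterior is not None
                   for p in self.placements for c in p.candidates):
                self.fields += OPT_FIELDS

    @property
    def checksum(self) -> str:
        return run_checksum(self.reference_tree, self.model_text)

    @property
    def n_edges(self) -> int:
        return len(re.findall(r"\{\d+\}", self.reference_tree))

    def validate(self):
        n = self.n_edges
        for p in self.placements:
            for c in p.candidates:
                if not 0 <= c.edge < n:
                    raise ValueError(
                        f"placement {p.query_name!r} refers to unknown edge {c.edge}")


def _cand_row(c: PlacementCandidate, fields):
    row = []
    for f in fields:
        attr = _FIELD_ATTR.get(f)
        row.append(getattr(c, attr) if attr else c.extras.get(f))
    return row


def _row_cand(row, fields):
    known = {}
    extras = {}
    for f, v in zip(fields, row):
        attr = _FIELD_ATTR.get(f)
        if attr:
            known[attr] = v
        else:
            extras[f] = v
    return PlacementCandidate(
        edge=int(known["edge"]), attach_a=known.get("attach_a"),
        pendant_b=known.get("pendant_b"), log_like=known.get("log_like"),
        log_marginal=known.get("log_marginal"), lwr=known.get("lwr"),
        posterior=known.get("posterior"), extras=extras)


def write_place(run: PlacementRun) -> str:
    run.validate()
    doc = {
        "version": run.format_version,
        "tree": run.reference_tree,
        "fields": run.fields,
        "placements": [],
        "metadata": {"model": run.model_text, "checksum": run.checksum},
    }
    for p in run.placements:
        entry = {"n": [p.query_name],
                 "p": [_cand_row(c, run.fields) for c in p.candidates]}
        if p.edpl is not None:
            entry["edpl"] = p.edpl
        doc["placements"].append(entry)
    return json.dumps(doc, indent=1)


def read_place(text: str) -> PlacementRun:
    doc = json.loads(text)
    version = str(doc.get("version", "?"))
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported placement file version {version!r}")
    fields = doc["fields"]
    placements = []
    for entry in doc["placements"]:
        cands = [_row_cand(row, fields) for row in entry["p"]]
        placements.append(QueryPlacement(entry["n"][0], cands,
                                         entry.get("edpl")))
    run = PlacementRun(doc["tree"], doc["metadata"]["model"], placements,
                       fields=fields, format_version=version)
    stored = doc["metadata"].get("checksum")
    if stored and stored != run.checksum:
        warnings.warn("placement file checksum does not match its tree/model")
    return run


def merge(runs: list) -> PlacementRun:
    """Union of placements from runs sharing one reference tree and model."""
    if not runs:
        raise ValueError("nothing to merge")
    first = runs[0]
    for other in runs[1:]:
        if other.checksum != first.checksum:
            raise ValueError(
                "cannot merge runs with different reference tree/model "
                f"(checksums {first.checksum[:12]} vs {other.checksum[:12]})")
    names = [p.query_name for r in runs for p in r.placements]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError("duplicate query names across runs: " + ", ".join(dupes))
    fields = first.fields
    merged = [p for r in runs for p in r.placements]
    return PlacementRun(first.reference_tree, first.model_text, merged,
                        fields=list(fields))


def split(run: PlacementRun, patterns: list) -> list:
    """Partition placements by the first matching name pattern.

    Returns one run per pattern plus a final remainder run for unmatched
    queries.
    """
    compiled = [re.compile(p) for p in patterns]
    buckets = [[] for _ in range(len(compiled) + 1)]
    for p in run.placements:
        for i, rx in enumerate(compiled):
            if rx.search(p.query_name):
                buckets[i].append(p)
                break
        else:
            buckets[-1].append(p)
    return [PlacementRun(run.reference_tree, run.model_text, b,
                         fields=list(run.fields)) for b in buckets]


def filter_run(run: PlacementRun, metric: str, bound: float) -> PlacementRun:
    """Keep queries whose best candidate passes the bound.

    ``lwr`` / ``posterior`` keep queries whose best value is >= the bound;
    ``edpl`` keeps queries with EDPL <= the bound.
    """
    if metric not in ("lwr", "posterior", "edpl"):
        raise ValueError(f"unknown filter metric {metric!r}")
    kept = []
    for p in run.placements:
        if metric == "edpl":
            if p.edpl is None:
                raise ValueError(f"no EDPL recorded for {p.query_name!r}")
            if p.edpl <= bound:
                kept.append(p)
        else:
            vals = [getattr(c, "lwr" if metric == "lwr" else "posterior")
                    for c in p.candidates]
            if any(v is None for v in vals):
                raise ValueError(
                    f"metric {metric!r} absent for {p.query_name!r}")
            if vals and max(vals) >= bound:
                kept.append(p)
    return PlacementRun(run.reference_tree, run.model_text, kept,
                        fields=list(run.fields))
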