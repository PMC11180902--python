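"""Serialization: cubes and configs in JSON/CSV, results as JSON or Markdown.

JSON is the canonical full-precision interchange format.  Each fuzzy number
is encoded as ``{"md": [[ell, upsilon], [ell, upsilon]], "nmd": [...]}``.
The CSV dialect is restricted to crisp linguistic terms (zero symbolic
translation, written ``J2``), which is how raw expert judgements are
typically published; full-precision intermediates must go through JSON.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import Any, Sequence

from .aggregation import WeightVector
from .algebra import TLIVqROFN
from .errors import DomainError, FormatError
from .linguistic import LinguisticScale, TwoTuple
from .mabac import DecisionCube, MabacResult, PipelineConfig

__all__ = [
    "number_to_json",
    "number_from_json",
    "load_cube",
    "save_cube",
    "load_config",
    "result_to_json",
    "result_from_json",
    "emit_report",
]


def _two_tuple_from_json(pair: Any, where: str) -> TwoTuple:
    try:
        ell, ups = pair
        return TwoTuple(int(ell), float(ups))
    except (TypeError, ValueError) as exc:
        raise FormatError(f"malformed 2-tuple {pair!r} at {where}") from exc


def number_to_json(R: TLIVqROFN) -> dict:
    return {
        "md": [[R.r.ell, R.r.upsilon], [R.t.ell, R.t.upsilon]],
        "nmd": [[R.u.ell, R.u.upsilon], [R.y.ell, R.y.upsilon]],
    }


def number_from_json(obj: Any, scale: LinguisticScale, where: str = "?") -> TLIVqROFN:
    if not isinstance(obj, dict) or "md" not in obj or "nmd" not in obj:
        raise FormatError(f"expected an md/nmd object at {where}, got {obj!r}")
    md, nmd = obj["md"], obj["nmd"]
    if len(md) != 2 or len(nmd) != 2:
        raise FormatError(f"md/nmd must each hold two 2-tuples at {where}")
    r = _two_tuple_from_json(md[0], where)
    t = _two_tuple_from_json(md[1], where)
    u = _two_tuple_from_json(nmd[0], where)
    y = _two_tuple_from_json(nmd[1], where)
    try:
        return TLIVqROFN(r, t, u, y, scale)
    except DomainError as exc:
        raise FormatError(f"invalid fuzzy number at {where}: {exc}") from exc


def _cube_from_doc(doc: dict) -> DecisionCube:
    try:
        tau = int(doc["tau"])
        raw = doc["cube"]
    except KeyError as exc:
        raise FormatError(f"cube document missing key {exc}") from exc
    scale = LinguisticScale(tau, tuple(doc["labels"]) if doc.get("labels") else None)
    entries = [
        [
            [
                number_from_json(cell, scale, where=f"(expert {g}, row {i}, col {j})")
                for j, cell in enumerate(row)
            ]
            for i, row in enumerate(mat)
        ]
        for g, mat in enumerate(raw)
    ]
    return DecisionCube.build(
        entries,
        expert_ids=doc.get("expert_ids"),
        alternative_ids=doc.get("alternative_ids"),
        attribute_ids=doc.get("attribute_ids"),
    )


def _cube_to_doc(cube: DecisionCube) -> dict:
    scale = cube.scale
    return {
        "tau": scale.tau,
        "labels": list(scale.labels) if scale.labels else None,
        "expert_ids": list(cube.expert_ids),
        "alternative_ids": list(cube.alternative_ids),
        "attribute_ids": list(cube.attribute_ids),
        "cube": [
            [[number_to_json(R) for R in row] for row in mat]
            for mat in cube.entries
        ],
    }


def _load_cube_csv(text: str) -> DecisionCube:
    """CSV dialect: columns expert, alternative, attribute, r, t, u, y, tau.

    Cells hold crisp terms like ``J2``; ``tau`` must be constant.
    """
    reader = csv.DictReader(_io.StringIO(text))
    required = {"expert", "alternative", "attribute", "r", "t", "u", "y", "tau"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise FormatError(
            f"cube CSV must have columns {sorted(required)}, got {reader.fieldnames}"
        )
    rows = list(reader)
    if not rows:
        raise FormatError("empty cube CSV")
    taus = {row["tau"] for row in rows}
    if len(taus) != 1:
        raise FormatError(f"inconsistent tau values in CSV: {sorted(taus)}")
    scale = LinguisticScale(int(taus.pop()))
    experts = list(dict.fromkeys(row["expert"] for row in rows))
    alts = list(dict.fromkeys(row["alternative"] for row in rows))
    attrs = list(dict.fromkeys(row["attribute"] for row in rows))
    cells: dict[tuple[str, str, str], TLIVqROFN] = {}
    for row in rows:
        where = f"({row['expert']}, {row['alternative']}, {row['attribute']})"
        tts = []
        for col in ("r", "t", "u", "y"):
            tt = TwoTuple.parse(row[col])
            if tt.upsilon != 0:
                raise FormatError(
                    f"CSV dialect admits only crisp terms; got {row[col]!r} at {where}"
                )
            if tt.ell > scale.tau:
                raise FormatError(
                    f"term index {tt.ell} exceeds tau={scale.tau} at {where}"
                )
            tts.append(tt)
        try:
            cells[(row["expert"], row["alternative"], row["attribute"])] = TLIVqROFN(
                *tts, scale
            )
        except DomainError as exc:
            raise FormatError(f"invalid fuzzy number at {where}: {exc}") from exc
    try:
        entries = [
            [[cells[(g, i, j)] for j in attrs] for i in alts] for g in experts
        ]
    except KeyError as exc:
        raise FormatError(f"missing CSV cell for {exc.args[0]}") from exc
    return DecisionCube.build(entries, experts, alts, attrs)


def load_cube(path: str | Path, format: str | None = None) -> DecisionCube:
    """Load a decision cube from JSON (canonical) or crisp-term CSV."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    text = path.read_text(encoding="utf-8").replace("−", "-")
    if fmt == "json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON in {path}: {exc}") from exc
        return _cube_from_doc(doc)
    if fmt == "csv":
        return _load_cube_csv(text)
    raise DomainError(f"unknown cube format {fmt!r}")


def save_cube(cube: DecisionCube, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        path.write_text(
            json.dumps(_cube_to_doc(cube), ensure_ascii=False, indent=1) + "\n",
            encoding="utf-8",
        )
        return
    if fmt == "csv":
        buf = _io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["expert", "alternative", "attribute", "r", "t", "u", "y", "tau"])
        for g, mat in enumerate(cube.entries):
            for i, row in enumerate(mat):
                for j, R in enumerate(row):
                    for tt in R.xi():
                        if tt != int(tt):
                            raise FormatError(
                                "CSV dialect admits only crisp terms; "
                                "use JSON for full precision"
                            )
                    writer.writerow(
                        [
                            cube.expert_ids[g],
                            cube.alternative_ids[i],
                            cube.attribute_ids[j],
                            *(f"J{int(x)}" for x in R.xi()),
                            cube.scale.tau,
                        ]
                    )
        path.write_text(buf.getvalue(), encoding="utf-8")
        return
    raise DomainError(f"unknown cube format {fmt!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config JSON.

    Keys: q, tau, expert_weights, attribute_weights, attribute_kinds,
    weight_policy (default as-given), validation (default warn),
    labels (optional).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON in {path}: {exc}") from exc
    try:
        policy = doc.get("weight_policy", "as-given")
        return PipelineConfig(
            q=float(doc["q"]),
            scale=LinguisticScale(
                int(doc["tau"]), tuple(doc["labels"]) if doc.get("labels") else None
            ),
            expert_weights=WeightVector(tuple(doc["expert_weights"]), policy=policy),
            attribute_weights=WeightVector(
                tuple(doc["attribute_weights"]), policy=policy
            ),
            attribute_kinds=tuple(doc["attribute_kinds"]),
            validation_mode=doc.get("validation", "warn"),
        )
    except KeyError as exc:
        raise FormatError(f"config missing key {exc}") from exc


def _matrix_to_json(matrix: Sequence[Sequence[TLIVqROFN]]) -> list:
    return [[number_to_json(R) for R in row] for row in matrix]


def result_to_json(result: MabacResult, version: str | None = None) -> dict:
    """Serialize every pipeline intermediate plus a provenance block."""
    from . import __version__

    cfg = result.config
    return {
        "alternative_ids": list(result.alternative_ids),
        "attribute_ids": list(result.attribute_ids),
        "aggregated": _matrix_to_json(result.aggregated),
        "normalized": _matrix_to_json(result.normalized),
        "weighted": _matrix_to_json(result.weighted),
        "baa": [number_to_json(g) for g in result.baa],
        "distances": [list(row) for row in result.distances],
        "cumulative": list(result.cumulative),
        "ranking": list(result.ranking),
        "provenance": {
            "version": version or __version__,
            "config": {
                "q": cfg.q,
                "tau": cfg.scale.tau,
                "labels": list(cfg.scale.labels) if cfg.scale.labels else None,
                "expert_weights": list(cfg.expert_weights.weights),
                "attribute_weights": list(cfg.attribute_weights.weights),
                "attribute_kinds": list(cfg.attribute_kinds),
                "weight_policy": cfg.expert_weights.policy,
                "validation": cfg.validation_mode,
            },
            "warnings": list(result.warnings),
        },
    }


def result_from_json(doc: dict) -> MabacResult:
    """Re-parse a serialized result into an equal :class:`MabacResult`."""
    prov = doc["provenance"]["config"]
    scale = LinguisticScale(
        int(prov["tau"]), tuple(prov["labels"]) if prov.get("labels") else None
    )
    cfg = PipelineConfig(
        q=float(prov["q"]),
        scale=scale,
        expert_weights=WeightVector(
            tuple(prov["expert_weights"]), policy=prov["weight_policy"]
        ),
        attribute_weights=WeightVector(
            tuple(prov["attribute_weights"]), policy=prov["weight_policy"]
        ),
        attribute_kinds=tuple(prov["attribute_kinds"]),
        validation_mode=prov["validation"],
    )

    def mat(key: str) -> list[list[TLIVqROFN]]:
        return [
            [number_from_json(cell, scale, where=f"{key}[{i}][{j}]")
             for j, cell in enumerate(row)]
            for i, row in enumerate(doc[key])
        ]

    return MabacResult(
        config=cfg,
        alternative_ids=tuple(doc["alternative_ids"]),
        attribute_ids=tuple(doc["attribute_ids"]),
        aggregated=mat("aggregated"),
        normalized=mat("normalized"),
        weighted=mat("weighted"),
        baa=[
            number_from_json(g, scale, where=f"baa[{j}]")
            for j, g in enumerate(doc["baa"])
        ],
        distances=[list(map(float, row)) for row in doc["distances"]],
        cumulative=[float(x) for x in doc["cumulative"]],
        ranking=tuple(doc["ranking"]),
        warnings=tuple(doc["provenance"]["warnings"]),
    )


def _fmt_number(R: TLIVqROFN) -> str:
    def tt(x: TwoTuple) -> str:
        return f"(J{x.ell}, {x.upsilon:.4f})"

    return f"([{tt(R.r)}, {tt(R.t)}], [{tt(R.u)}, {tt(R.y)}])"


def _md_matrix(
    title: str,
    matrix: Sequence[Sequence[TLIVqROFN]],
    row_ids: Sequence[str],
    col_ids: Sequence[str],
) -> list[str]:
    lines = [f"## {title}", ""]
    lines.append("| | " + " | ".join(col_ids) + " |")
    lines.append("|" + "---|" * (len(col_ids) + 1))
    for rid, row in zip(row_ids, matrix):
        lines.append(f"| {rid} | " + " | ".join(_fmt_number(R) for R in row) + " |")
    lines.append("")
    return lines


def emit_report(result: MabacResult, format: str = "markdown") -> str:
    """Render a result as a Markdown document or a JSON string.

    Markdown shows every intermediate table at 4-decimal display precision,
    the cumulative values, the ranking chain and any warnings; the
    underlying result keeps full precision.
    """
    if format == "json":
        return json.dumps(result_to_json(result), ensure_ascii=False, indent=1)
    if format != "markdown":
        raise DomainError(f"unknown report format {format!r}")
    alt = result.alternative_ids
    att = result.attribute_ids
    lines = ["# MABAC decision report", ""]
    cfg = result.config
    lines.append(
        f"q = {cfg.q:g}, tau = {cfg.scale.tau}, "
        f"{len(alt)} alternatives x {len(att)} attributes"
    )
    lines.append("")
    lines += _md_matrix("Aggregated matrix", result.aggregated, alt, att)
    lines += _md_matrix("Weighted normalized matrix", result.weighted, alt, att)
    lines += _md_matrix("Border approximation area", [result.baa], ["g"], att)
    lines += ["## Signed distances to the border", ""]
    lines.append("| | " + " | ".join(att) + " | S |")
    lines.append("|" + "---|" * (len(att) + 2))
    for rid, drow, s in zip(alt, result.distances, result.cumulative):
        lines.append(
            f"| {rid} | "
            + " | ".join(f"{d:.4f}" for d in drow)
            + f" | {s:.4f} |"
        )
    lines.append("")
    lines.append("## Ranking")
    lines.append("")
    lines.append(" > ".join(result.ranking))
    lines.append("")
    lines.append("## Warnings")
    lines.append("")
    if result.warnings:
        lines.extend(f"- {w}" for w in result.warnings)
    else:
        lines.append("(none)")
    lines.append("")
    return "\n".join(lines)
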