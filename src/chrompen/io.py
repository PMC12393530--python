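"""Readers and writers for the formats the tool touches.

* BEDPE loop/contact lists (6+ whitespace-separated columns, ``#`` comments).
  Coordinates are 0-based half-open; anchor distance is midpoint-to-midpoint.
* Score tables: TSV with header; anchors and/or a precomputed ``distance_bp``
  column plus ``raw_score``.  Unknown extra columns are preserved.
* Penalty parameter files: JSON with the schema
  ``{"species", "fit_range_bp", "normalization",
  "components": [{"pi", "beta", "alpha"}, ...]}`` plus optional metadata.
* Binned decay profiles: TSV with ``bin_start_bp, bin_end_bp, bin_mid_bp, value``.

All writers are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import logging
import math
import os
import tempfile
import warnings
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .types import (
    ANCHOR_COLUMNS,
    ContactRecord,
    ContactSet,
    DecayProfile,
    GenomicInterval,
    PenaltyParams,
    PowerLawComponent,
    ScoreTable,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, "os.PathLike[str]"]


def atomic_write_text(path: PathLike, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file in the same directory."""
    path = os.fspath(path)
    directory = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-", suffix="~")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# BEDPE contact lists
# ---------------------------------------------------------------------------

def _parse_coord(token: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer {what} {token!r}") from None


def read_bedpe(path: PathLike,
               min_distance_bp: Optional[float] = None,
               max_distance_bp: Optional[float] = None,
               source_label: Optional[str] = None) -> ContactSet:
    """Read a BEDPE loop list into a :class:`ContactSet`.

    Cis rows only; trans (inter-chromosomal) rows are dropped with a logged
    count since the decay model is strictly a function of linear distance.
    Column 7 (or 8, when 7 is a non-numeric name field) is taken as the
    contact count/weight when numeric; otherwise each row counts once.
    Rows are filtered to the closed interval ``[min, max]`` when given.
    """
    records: list[ContactRecord] = []
    n_trans = 0
    lo = -math.inf if min_distance_bp is None else float(min_distance_bp)
    hi = math.inf if max_distance_bp is None else float(max_distance_bp)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"line {lineno}: expected >= 6 BEDPE columns, got {len(fields)}"
                )
            c1, s1, e1, c2, s2, e2 = fields[:6]
            s1i = _parse_coord(s1, lineno, "start1")
            e1i = _parse_coord(e1, lineno, "end1")
            s2i = _parse_coord(s2, lineno, "start2")
            e2i = _parse_coord(e2, lineno, "end2")
            if e1i <= s1i or e2i <= s2i:
                raise ParseError(f"line {lineno}: interval end must exceed start")
            if c1 != c2:
                n_trans += 1
                continue
            count = 1.0
            for idx in (6, 7):
                if len(fields) > idx:
                    try:
                        count = float(fields[idx])
                        break
                    except ValueError:
                        continue
            if not (count >= 0 and math.isfinite(count)):
                raise ParseError(f"line {lineno}: count must be finite and >= 0")
            distance = abs(0.5 * (s2i + e2i) - 0.5 * (s1i + e1i))
            if not (lo <= distance <= hi):
                continue
            try:
                records.append(ContactRecord(
                    GenomicInterval(c1, s1i, e1i),
                    GenomicInterval(c2, s2i, e2i),
                    count=count,
                ))
            except ValidationError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    if n_trans:
        logger.info("read_bedpe(%s): dropped %d trans rows", path, n_trans)
    if not records:
        warnings.warn(
            f"read_bedpe({os.fspath(path)}): no cis records survive the "
            f"distance filter [{lo}, {hi}]",
            stacklevel=2,
        )
    label = source_label if source_label is not None else os.path.basename(os.fspath(path))
    return ContactSet(records, source_label=label, n_trans_dropped=n_trans)


def write_bedpe(contacts: ContactSet, path: PathLike) -> None:
    """Write a ContactSet as 7-column BEDPE (column 7 = count)."""
    lines = []
    for r in contacts.records:
        lines.append("\t".join([
            r.anchor1.chrom, str(r.anchor1.start), str(r.anchor1.end),
            r.anchor2.chrom, str(r.anchor2.start), str(r.anchor2.end),
            repr(r.count),
        ]))
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def read_score_table(path: PathLike, score_kind: str = "other") -> ScoreTable:
    """Read a TSV score table.

    Requires ``raw_score`` and either ``distance_bp`` or the six anchor
    columns; when ``distance_bp`` is absent it is computed as the
    midpoint-to-midpoint anchor separation.  Row numbers in error messages
    are 1-based data rows (excluding the header).
    """
    df = pd.read_csv(path, sep="\t")
    if "raw_score" not in df.columns:
        raise SchemaError(
            "score table is missing 'raw_score'; expected columns: "
            f"{','.join(ANCHOR_COLUMNS)}[,distance_bp],raw_score[,penalized_score]"
        )
    has_anchors = all(c in df.columns for c in ANCHOR_COLUMNS)
    if "distance_bp" not in df.columns:
        if not has_anchors:
            missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
            raise SchemaError(
                "score table needs either a 'distance_bp' column or the anchor "
                f"columns {','.join(ANCHOR_COLUMNS)} (missing: {','.join(missing)})"
            )
        mid1 = 0.5 * (df["start1"].astype(float) + df["end1"].astype(float))
        mid2 = 0.5 * (df["start2"].astype(float) + df["end2"].astype(float))
        df["distance_bp"] = (mid2 - mid1).abs()
    for col in ("distance_bp", "raw_score"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"row {row + 1}: non-numeric {col} value {df[col].iloc[row]!r}"
            )
        df[col] = numeric
    d = df["distance_bp"].to_numpy(dtype=float)
    if len(d) and not np.all(d > 0):
        row = int(np.flatnonzero(~(d > 0))[0])
        raise ParseError(f"row {row + 1}: distance_bp must be > 0, got {d[row]}")
    return ScoreTable(df, score_kind=score_kind)


def write_score_table(table: ScoreTable, path: PathLike) -> None:
    atomic_write_text(path, table.df.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# Penalty parameter JSON
# ---------------------------------------------------------------------------

def _require(obj: dict, key: str, context: str):
    if key not in obj:
        raise SchemaError(f"{context}: missing required key {key!r}")
    return obj[key]


def read_params(path: PathLike) -> PenaltyParams:
    """Read a penalty-parameter JSON file (schema in the module docstring)."""
    with open(path) as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict):
        raise SchemaError("params file must contain a JSON object")
    comps_raw = _require(obj, "components", "params")
    if not isinstance(comps_raw, list) or not comps_raw:
        raise SchemaError("params: 'components' must be a non-empty array")
    comps = []
    for i, c in enumerate(comps_raw):
        pi = float(_require(c, "pi", f"components[{i}]"))
        beta = float(_require(c, "beta", f"components[{i}]"))
        alpha = float(_require(c, "alpha", f"components[{i}]"))
        if not all(map(math.isfinite, (pi, beta, alpha))):
            raise ValidationError(f"components[{i}]: pi/beta/alpha must be finite")
        x_range = tuple(c["x_range"]) if c.get("x_range") is not None else None
        comps.append(PowerLawComponent(alpha=alpha, beta=beta, pi=pi,
                                       x_range=x_range,
                                       r_squared=c.get("r_squared")))
    fit_range = _require(obj, "fit_range_bp", "params")
    try:
        return PenaltyParams(
            species_label=str(_require(obj, "species", "params")),
            components=tuple(comps),
            fit_range_bp=(float(fit_range[0]), float(fit_range[1])),
            normalization=obj.get("normalization", "max_one_on_fit_range"),
            selection_table=tuple(obj.get("selection_table", ())),
            transitions_bp=tuple(obj.get("transitions_bp", ())),
            seed=obj.get("seed"),
            generated_by=obj.get("generated_by"),
        )
    except (TypeError, IndexError) as exc:
        raise SchemaError(f"params: malformed field ({exc})") from None


def params_to_json(params: PenaltyParams) -> str:
    """Serialize params deterministically (byte-identical for equal params)."""
    obj: dict = {
        "species": params.species_label,
        "fit_range_bp": list(params.fit_range_bp),
        "normalization": params.normalization,
        "components": [
            {
                "pi": c.pi,
                "beta": c.beta,
                "alpha": c.alpha,
                "x_range": list(c.x_range) if c.x_range is not None else None,
                "r_squared": c.r_squared,
            }
            for c in params.components
        ],
        "n_components": params.n_components,
        "selection_table": list(params.selection_table),
        "transitions_bp": list(params.transitions_bp),
        "seed": params.seed,
    }
    if params.generated_by is not None:
        obj["generated_by"] = params.generated_by
    return json.dumps(obj, indent=2) + "\n"


def write_params(params: PenaltyParams, path: PathLike) -> None:
    atomic_write_text(path, params_to_json(params))


# ---------------------------------------------------------------------------
# Binned profiles
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ("bin_start_bp", "bin_end_bp", "bin_mid_bp", "value")


def write_profile(profile: DecayProfile, path: PathLike) -> None:
    df = pd.DataFrame({
        "bin_start_bp": profile.bin_edges_bp[:-1],
        "bin_end_bp": profile.bin_edges_bp[1:],
        "bin_mid_bp": profile.bin_mid_bp,
        "value": profile.values,
    })
    atomic_write_text(path, df.to_csv(sep="\t", index=False, float_format="%.17g"))


def read_profile(path: PathLike, source_label: str = "") -> DecayProfile:
    """Read a binned profile TSV; bins must be sorted, contiguous, non-overlapping."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"profile is missing columns: {','.join(missing)}")
    starts = df["bin_start_bp"].to_numpy(dtype=float)
    ends = df["bin_end_bp"].to_numpy(dtype=float)
    if len(starts) == 0:
        return DecayProfile(np.array([]), np.array([]), np.array([]),
                            source_label=source_label)
    if np.any(ends <= starts):
        raise ValidationError("profile bins must have end > start")
    if np.any(np.diff(starts) <= 0):
        raise ValidationError("profile bins must be sorted by start and non-overlapping")
    if not np.allclose(ends[:-1], starts[1:], rtol=0, atol=1e-6):
        raise ValidationError("profile bins must be contiguous (end[i] == start[i+1])")
    edges = np.concatenate([starts, ends[-1:]])
    return DecayProfile(edges, df["bin_mid_bp"].to_numpy(dtype=float),
                        df["value"].to_numpy(dtype=float), source_label=source_label)
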