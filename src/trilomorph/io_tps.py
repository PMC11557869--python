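"""Reading and writing tpsDIG2-dialect curve files, metadata tables and results.

The TPS dialect accepted here is the outline flavour: blocks introduced by an
``LM=`` line (usually ``LM=0``), followed by ``CURVES=n`` and, per curve,
``POINTS=k`` and k whitespace-separated ``x y`` lines, closed by an ``ID=``
line.  ``IMAGE=``, ``COMMENT=`` are ignored; ``SCALE=`` is parsed but unused
downstream (the analysis is scale-free after coefficient normalization).
Coordinates are treated as y-up planar; no image-row flipping is performed —
digitizer convention is the caller's responsibility.

Structural corruption (a declared point count that does not match the block)
raises; biological invalidity (a record without exactly two curves) only flags
the record, so datasets with stray landmarks-only blocks survive a read.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ORDER_LABELS = (
    "Asaphida",
    "Aulacopleurida",
    "Corynexochida",
    "Harpida",
    "Lichida",
    "Odontopleurida",
    "Olenida",
    "Phacopida",
    "Proetida",
    "Redlichiida",
    "Trinucleida",
    "Unassigned",
)

PERIOD_LABELS = (
    "Cambrian",
    "Ordovician",
    "Silurian",
    "Devonian",
    "Carboniferous",
    "Permian",
)

#: Orders folded into the "Unassigned" bucket on read (paraphyletic wastebasket
#: taxa that cannot be treated as a coherent group).
ORDER_SYNONYMS = {"Ptychopariida": "Unassigned"}


class TPSFormatError(ValueError):
    """Structurally malformed TPS file (point counts, stray coordinates...)."""


class MetadataError(ValueError):
    """Metadata table fails vocabulary or uniqueness validation."""


@dataclass
class RawSpecimenRecord:
    """One TPS block: an id plus its ordered digitized curves."""

    id: str
    curves: list[np.ndarray]
    image_ref: str | None = None
    scale: float | None = None
    valid: bool = True
    invalid_reason: str | None = None

    def __post_init__(self) -> None:
        self.curves = [np.asarray(c, dtype=float) for c in self.curves]
        for c in self.curves:
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 2:
                raise TPSFormatError(
                    f"record {self.id!r}: each curve needs >= 2 (x, y) points"
                )
            if not np.all(np.isfinite(c)):
                raise TPSFormatError(f"record {self.id!r}: non-finite coordinate")
        if len(self.curves) != 2:
            self.valid = False
            self.invalid_reason = (
                f"expected 2 curves for a cephalon record, got {len(self.curves)}"
            )


@dataclass(frozen=True)
class SpecimenMetadata:
    id: str
    species: str
    order_label: str
    period_label: str


_KEY_RE = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def _parse_float_pair(line: str, path: str, lineno: int) -> tuple[float, float]:
    parts = line.split()
    if len(parts) != 2:
        raise TPSFormatError(f"{path}:{lineno}: expected 'x y', got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise TPSFormatError(f"{path}:{lineno}: non-numeric coordinate {line!r}") from exc


def read_tps(path: str | Path) -> list[RawSpecimenRecord]:
    """Parse a tpsDIG2 curve file into raw specimen records.

    Every coordinate is accounted for: a block whose parsed point count does
    not match its ``POINTS=`` declarations raises :class:`TPSFormatError`
    naming the offending block.  Records that are structurally sound but do
    not carry exactly two curves are returned with ``valid=False``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[RawSpecimenRecord] = []

    block_index = 0
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        m = _KEY_RE.match(line)
        if not (m and m.group(1).upper() == "LM"):
            raise TPSFormatError(f"{path}:{i + 1}: expected LM= to start a block")
        block_index += 1
        n_landmarks = int(m.group(2))
        i += 1
        # landmark points (usually zero for pure outline files) are read and
        # discarded — they are not part of the outline pipeline
        for _ in range(n_landmarks):
            if i >= n:
                raise TPSFormatError(f"{path}: block {block_index}: truncated landmarks")
            _parse_float_pair(lines[i], str(path), i + 1)
            i += 1

        curves: list[np.ndarray] = []
        declared_curves: int | None = None
        rec_id: str | None = None
        image_ref: str | None = None
        scale: float | None = None

        while i < n:
            line = lines[i]
            if not line.strip():
                i += 1
                continue
            m = _KEY_RE.match(line)
            if m is None:
                raise TPSFormatError(
                    f"{path}:{i + 1}: stray coordinate line outside a POINTS block"
                )
            key = m.group(1).upper()
            val = m.group(2)
            if key == "LM":
                break  # next block
            i += 1
            if key == "CURVES":
                declared_curves = int(val)
            elif key == "POINTS":
                k = int(val)
                pts = np.empty((k, 2), dtype=float)
                for j in range(k):
                    if i >= n or _KEY_RE.match(lines[i]):
                        raise TPSFormatError(
                            f"{path}: block {block_index} (id={rec_id!r}): "
                            f"POINTS={k} declared but only {j} points present"
                        )
                    pts[j] = _parse_float_pair(lines[i], str(path), i + 1)
                    i += 1
                # any extra coordinate rows would hit the "stray coordinate"
                # branch above on the next iteration
                curves.append(pts)
            elif key == "ID":
                rec_id = val
            elif key == "IMAGE":
                image_ref = val
            elif key == "SCALE":
                scale = float(val)
            elif key == "COMMENT":
                pass
            else:
                pass  # unknown keys tolerated, per tpsDIG2 variant sprawl

        if declared_curves is not None and declared_curves != len(curves):
            raise TPSFormatError(
                f"{path}: block {block_index} (id={rec_id!r}): CURVES="
                f"{declared_curves} but {len(curves)} POINTS blocks parsed"
            )
        if rec_id is None:
            rec_id = f"block_{block_index}"
        records.append(
            RawSpecimenRecord(id=rec_id, curves=curves, image_ref=image_ref, scale=scale)
        )
    return records


def _fmt(v: float) -> str:
    # shortest round-trip decimal representation: read(write(x)) == x exactly,
    # which also makes write -> read -> write byte-idempotent
    return repr(float(v))


def write_tps(records: Sequence[RawSpecimenRecord], path: str | Path) -> None:
    """Serialize records in the same outline dialect :func:`read_tps` accepts."""
    path = Path(path)
    out: list[str] = []
    for rec in records:
        out.append("LM=0")
        out.append(f"CURVES={len(rec.curves)}")
        for curve in rec.curves:
            out.append(f"POINTS={len(curve)}")
            for x, y in curve:
                out.append(f"{_fmt(x)} {_fmt(y)}")
        if rec.image_ref is not None:
            out.append(f"IMAGE={rec.image_ref}")
        if rec.scale is not None:
            out.append(f"SCALE={_fmt(rec.scale)}")
        out.append(f"ID={rec.id}")
    path.write_text("\n".join(out) + "\n")


DEFAULT_COLUMNS = {"id": "id", "species": "species", "order": "order", "period": "period"}


def read_metadata(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[SpecimenMetadata]:
    """Read a specimen metadata table (CSV/TSV with header).

    ``columns`` maps the canonical names ``id, species, order, period`` to the
    file's actual column headers, so deposited tables with other layouts can be
    read without editing them.  Order labels are validated against the closed
    12-level vocabulary (with historical 'Ptychopariida' folded into
    'Unassigned'), periods against the six Palaeozoic periods.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")

    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing columns {missing}; have {list(df.columns)}")

    out: list[SpecimenMetadata] = []
    seen: set[str] = set()
    for row_idx, row in df.iterrows():
        sid = row[colmap["id"]].strip()
        order = row[colmap["order"]].strip()
        period = row[colmap["period"]].strip()
        order = ORDER_SYNONYMS.get(order, order)
        if order not in ORDER_LABELS:
            raise MetadataError(
                f"{path} row {row_idx}: unknown order label {order!r} (id={sid!r})"
            )
        if period not in PERIOD_LABELS:
            raise MetadataError(
                f"{path} row {row_idx}: unknown period label {period!r} (id={sid!r})"
            )
        if sid in seen:
            raise MetadataError(f"{path} row {row_idx}: duplicate specimen id {sid!r}")
        seen.add(sid)
        out.append(
            SpecimenMetadata(
                id=sid,
                species=row[colmap["species"]].strip(),
                order_label=order,
                period_label=period,
            )
        )
    return out


def write_metadata(metadata: Sequence[SpecimenMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [m.id for m in metadata],
            "species": [m.species for m in metadata],
            "order": [m.order_label for m in metadata],
            "period": [m.period_label for m in metadata],
        }
    )
    df.to_csv(path, index=False)


@dataclass
class ResultManifest:
    out_dir: Path
    files: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "files": self.files,
                "config": self.config,
                "seed": self.seed,
                "software": {"name": "trilomorph", "version": _version()},
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def _version() -> str:
    from trilomorph import __version__

    return __version__


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    overwrite: bool = False,
) -> ResultManifest:
    """Write one CSV per named table plus a JSON run manifest.

    Re-running with identical tables and config produces byte-identical
    files (no timestamps are recorded).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = ResultManifest(out_dir=out_dir, config=dict(config or {}), seed=seed)
    for name, df in tables.items():
        fname = f"{name}.csv"
        target = out_dir / fname
        if target.exists() and not overwrite:
            raise FileExistsError(f"{target} exists; pass overwrite=True to replace")
        df.to_csv(target, index=True)
        manifest.files[name] = fname
    man_path = out_dir / "manifest.json"
    if man_path.exists() and not overwrite:
        raise FileExistsError(f"{man_path} exists; pass overwrite=True to replace")
    man_path.write_text(manifest.to_json() + "\n")
    return manifest
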