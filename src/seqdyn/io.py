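"""Readers and writers for on-disk artifacts.

Formats
-------
FASTA
    Standard, via Biopython; the record id becomes the protein id.
R2 table
    Tab-separated with a required header ``index  aa  r2  [flag]``.
    1-based residue index, one-letter amino acid (checked against the
    companion sequence), rate in s^-1.  Missing values are an empty field or
    ``NA``; any non-empty flag excludes the row from scoring; ``#`` starts a
    comment line.  Absent rows are treated as unobserved.
ss2
    PsiPred VFORMAT: optional preamble, then ``index aa state coil helix
    strand`` rows; the helix column is extracted and validated against the
    sequence.
Parameter file
    Flat key-value text: one line per amino acid (``A<TAB>1.0123``), a ``b``
    line, optional ``#`` comments and ``meta_*`` entries.  Values are written
    with full precision (repr) so a write/read cycle is bit-exact.
Manifest
    YAML listing per-protein paths and the train/test role.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .params import AMINO_ACIDS, ModelParameters
from .records import ProteinRecord, default_mask

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_r2_table",
    "write_r2_table",
    "read_ss2",
    "write_ss2",
    "read_params",
    "write_params",
    "read_manifest",
    "load_manifest_dataset",
    "write_dataset",
    "load_table1",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """All (id, sequence) pairs from a FASTA file, uppercased."""
    out = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(path, records: Sequence[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_r2_table(path, sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Measured R2 array (NaN where unobserved) and scoring mask for a
    sequence.  Rows are validated against the sequence: a residue-letter
    mismatch is a hard error naming the position."""
    n = len(sequence)
    values = np.full(n, np.nan)
    excluded = np.zeros(n, dtype=bool)
    seen_header = False
    last_index = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        # split before stripping: a missing trailing r2/flag cell is meaningful
        fields = raw.rstrip("\r\n").split("\t")
        if not seen_header:
            if [f.lower() for f in fields[:3]] != ["index", "aa", "r2"]:
                raise ValueError(
                    f"{path}:{lineno}: expected header 'index\\taa\\tr2[\\tflag]', got {raw!r}"
                )
            seen_header = True
            continue
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected at least 3 fields, got {len(fields)}")
        idx = int(fields[0])
        if idx < 1 or idx > n:
            raise ValueError(
                f"{path}:{lineno}: residue index {idx} outside sequence length {n}"
            )
        if idx <= last_index:
            raise ValueError(
                f"{path}:{lineno}: residue indices must be strictly increasing "
                f"({idx} after {last_index})"
            )
        last_index = idx
        if fields[1] != sequence[idx - 1]:
            raise ValueError(
                f"{path}:{lineno}: amino acid {fields[1]!r} at position {idx} "
                f"does not match sequence letter {sequence[idx - 1]!r}"
            )
        cell = fields[2].strip()
        if cell and cell.upper() != "NA":
            values[idx - 1] = float(cell)
        if len(fields) > 3 and fields[3].strip():
            excluded[idx - 1] = True
    if not seen_header:
        raise ValueError(f"{path}: empty R2 table (header required)")
    mask = default_mask(sequence, values) & ~excluded
    return values, mask


def write_r2_table(
    path,
    sequence: str,
    values: np.ndarray,
    mask: Optional[np.ndarray] = None,
    flags: Optional[Sequence[str]] = None,
) -> None:
    values = np.asarray(values, dtype=float)
    lines = ["index\taa\tr2\tflag"]
    for i, aa in enumerate(sequence):
        cell = "" if not math.isfinite(values[i]) else repr(float(values[i]))
        flag = ""
        if flags is not None and flags[i]:
            flag = flags[i]
        elif mask is not None and not mask[i] and aa != "P" and cell:
            flag = "excluded"
        lines.append(f"{i + 1}\t{aa}\t{cell}\t{flag}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ss2(path, sequence: str) -> np.ndarray:
    """Per-residue helix-propensity column from a PsiPred ss2 file.

    Preamble lines are skipped until the first row matching the columnar
    pattern; residue letters and total length are validated against the
    sequence."""
    n = len(sequence)
    scores = np.full(n, np.nan)
    count = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        fields = raw.split()
        if len(fields) < 6:
            continue
        try:
            idx = int(fields[0])
            coil, helix, strand = float(fields[3]), float(fields[4]), float(fields[5])
        except ValueError:
            continue
        if idx < 1 or idx > n:
            raise ValueError(f"{path}:{lineno}: residue index {idx} outside sequence length {n}")
        aa = fields[1]
        if aa != sequence[idx - 1]:
            raise ValueError(
                f"{path}:{lineno}: residue {aa!r} at position {idx} does not match "
                f"sequence letter {sequence[idx - 1]!r}"
            )
        if not 0.0 <= helix <= 1.0:
            raise ValueError(f"{path}:{lineno}: helix score {helix} outside [0, 1]")
        scores[idx - 1] = helix
        count += 1
    if count != n:
        raise ValueError(
            f"{path}: ss2 file has {count} data rows but the sequence has {n} residues"
        )
    return scores


def write_ss2(path, sequence: str, helix_scores: np.ndarray) -> None:
    """Write a minimal PsiPred-style ss2 file (3-decimal scores, helix in
    the standard column; coil takes the remaining weight, strand 0)."""
    scores = np.asarray(helix_scores, dtype=float)
    lines = ["# PSIPRED VFORMAT (SS2)", ""]
    for i, aa in enumerate(sequence):
        h = scores[i]
        state = "H" if h >= 0.5 else "C"
        lines.append(f"{i + 1:4d} {aa} {state}   {max(0.0, 1 - h):.3f}  {h:.3f}  {0.0:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path) -> ModelParameters:
    """Model parameters from a flat key-value file; requires all 20 amino
    acids and ``b``, all positive."""
    q: dict[str, float] = {}
    b: Optional[float] = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        key = key.strip()
        if key.startswith("meta_"):
            continue
        try:
            number = float(value)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: cannot parse value {value!r} for {key!r}")
        if key == "b":
            b = number
        elif key in AMINO_ACIDS:
            q[key] = number
        else:
            raise ValueError(f"{path}:{lineno}: unknown parameter key {key!r}")
    if b is None:
        raise ValueError(f"{path}: missing required parameter 'b'")
    missing = sorted(set(AMINO_ACIDS) - set(q))
    if missing:
        raise ValueError(f"{path}: missing q entries for {missing}")
    return ModelParameters(q=q, b=b)  # positivity enforced by the container


def write_params(path, params: ModelParameters, metadata: Optional[dict] = None) -> None:
    lines = []
    for key, value in (metadata or {}).items():
        lines.append(f"meta_{key}\t{value}")
    for aa in AMINO_ACIDS:
        lines.append(f"{aa}\t{params.q[aa]!r}")
    lines.append(f"b\t{params.b!r}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ManifestEntry:
    id: str
    fasta: Path
    r2: Optional[Path]
    ss2: Optional[Path]
    role: str


def read_manifest(path) -> list[ManifestEntry]:
    """Dataset manifest: YAML with a ``proteins`` list of mappings carrying
    ``id``, ``fasta``, optional ``r2`` and ``ss2`` paths (relative to the
    manifest), and ``role`` (train or test, default train)."""
    path = Path(path)
    payload = yaml.safe_load(path.read_text())
    if not isinstance(payload, dict) or "proteins" not in payload:
        raise ValueError(f"{path}: manifest must be a mapping with a 'proteins' list")
    base = path.parent
    entries = []
    for i, item in enumerate(payload["proteins"]):
        if not isinstance(item, dict) or "id" not in item or "fasta" not in item:
            raise ValueError(f"{path}: proteins[{i}] must be a mapping with 'id' and 'fasta'")
        role = item.get("role", "train")
        if role not in ("train", "test"):
            raise ValueError(f"{path}: proteins[{i}] role must be 'train' or 'test', got {role!r}")
        entries.append(
            ManifestEntry(
                id=str(item["id"]),
                fasta=base / item["fasta"],
                r2=base / item["r2"] if item.get("r2") else None,
                ss2=base / item["ss2"] if item.get("ss2") else None,
                role=role,
            )
        )
    if not entries:
        raise ValueError(f"{path}: manifest lists no proteins")
    return entries


def load_manifest_dataset(path) -> list[tuple[ProteinRecord, str]]:
    """Load every manifest entry into a (record, role) pair."""
    out = []
    for entry in read_manifest(path):
        pairs = read_fasta(entry.fasta)
        match = [s for name, s in pairs if name == entry.id] or [pairs[0][1]]
        sequence = match[0]
        measured = mask = scores = None
        if entry.r2 is not None:
            measured, mask = read_r2_table(entry.r2, sequence)
        if entry.ss2 is not None:
            scores = read_ss2(entry.ss2, sequence)
        out.append(
            (
                ProteinRecord(
                    id=entry.id,
                    sequence=sequence,
                    measured_r2=measured,
                    mask=mask,
                    helix_scores=scores,
                ),
                entry.role,
            )
        )
    return out


def write_dataset(directory, records: Sequence[ProteinRecord], role: str = "train") -> Path:
    """Write records as FASTA + R2 tables + a manifest under ``directory``;
    returns the manifest path.  The synthetic generator and the readers meet
    here, so synthetic runs exercise the same I/O as real data."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    proteins = []
    for record in records:
        fasta = directory / f"{record.id}.fasta"
        write_fasta(fasta, [(record.id, record.sequence)])
        entry = {"id": record.id, "fasta": fasta.name, "role": role}
        if record.measured_r2 is not None:
            table = directory / f"{record.id}.r2.tsv"
            write_r2_table(table, record.sequence, record.measured_r2, record.mask)
            entry["r2"] = table.name
        proteins.append(entry)
    manifest = directory / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"proteins": proteins}, sort_keys=False))
    return manifest


def load_table1() -> pd.DataFrame:
    """The bundled benchmark summary table (one row per protein: dataset
    split, residue count, conditions, mean/sd of measured R2, prediction
    RMSE, and the helix-boosted RMSE where one was reported)."""
    with resources.files("seqdyn.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    expected = {"name", "set", "n_res", "mean_r2", "sd_r2", "rmse"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"bundled table is malformed; missing {sorted(missing)}")
    return df
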