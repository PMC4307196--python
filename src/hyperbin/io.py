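"""File ingestion and export: FASTA, lineage tables, reference
fragmenting, model persistence, and result/composition writers.

The model file is a single HDF5 container (magic bytes and versioning
come with the format) holding the architecture, float32 prototypes
(gzip + byte-shuffle compressed), per-rank label tables, and all
hyperparameters; the lattice geometry is a pure function of (s, r) and
is rebuilt on load. The default architecture (k=4, s=8, r=5) stays well
under 5 MB on disk.
"""

from __future__ import annotations

import csv
import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Union

import h5py
import numpy as np
from Bio import SeqIO

from .classify import (
    RANKS,
    REJECT,
    Assignment,
    ClassifierConfig,
    Lineage,
    NodeLabels,
)
from .errors import (
    FastaParseError,
    InvalidParameterError,
    LineageValidationError,
    ModelFormatError,
)
from .kmers import CorpusTermStats
from .lattice import build_lattice
from .model import FORMAT_VERSION, H2SOMModel
from .som import TrainingConfig

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "read_lineages",
    "write_lineages",
    "fragment_reference",
    "save_model",
    "load_model",
    "write_assignments",
    "write_krona_text",
]

FRAGMENT_MODES = ("fixed15kb", "fixed4kb", "half", "quarter")
MIN_REFERENCE_LENGTH = 4000  # only sequences exceeding 4 kb enter a model


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    sequence: str


def _open_maybe_gzip(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: Union[str, Path]) -> List[SequenceRecord]:
    """Parse a multi-record FASTA file (plain or gzip)."""
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    with _open_maybe_gzip(path) as fh:
        lines_seen = 0
        for line in fh:
            lines_seen += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}:{lines_seen}: expected a '>' header, "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")
    records: List[SequenceRecord] = []
    seen = set()
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(
                SequenceRecord(rec.id, rec.description, str(rec.seq))
            )
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 70
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_lineages(path: Union[str, Path]) -> Dict[str, Lineage]:
    """Read a tab-separated lineage table: id, superkingdom, phylum,
    class, order. Empty cells are allowed only as a trailing suffix
    (no gaps); duplicate ids are an error. A first line starting with
    'id<TAB>' is tolerated as a header."""
    lineages: Dict[str, Lineage] = {}
    with _open_maybe_gzip(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row_no, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row_no == 1 and row[0].strip().lower() == "id":
                continue
            sid = row[0].strip()
            if not sid:
                raise LineageValidationError(f"{path}:{row_no}: empty id")
            if sid in lineages:
                raise LineageValidationError(
                    f"{path}:{row_no}: duplicate id {sid!r}"
                )
            cells = [c.strip() for c in row[1 : 1 + len(RANKS)]]
            cells += [""] * (len(RANKS) - len(cells))
            taxa: List[str] = []
            seen_empty = False
            for rank, cell in zip(RANKS, cells):
                if cell == "":
                    seen_empty = True
                elif seen_empty:
                    raise LineageValidationError(
                        f"{path}:{row_no}: rank {rank!r} present but a "
                        f"higher rank is empty (gap)"
                    )
                else:
                    taxa.append(cell)
            if not taxa:
                raise LineageValidationError(
                    f"{path}:{row_no}: lineage has no ranks at all"
                )
            lineages[sid] = Lineage(tuple(taxa))
    return lineages


def write_lineages(
    lineages: Mapping[str, Lineage], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for sid, lin in lineages.items():
            cells = [lin.get(rank) or "" for rank in RANKS]
            fh.write("\t".join([sid, *cells]) + "\n")


def fragment_reference(
    records: Sequence[SequenceRecord], mode: str
) -> List[SequenceRecord]:
    """Cut reference sequences into training fragments.

    Records of length <= 4000 nt are dropped entirely (only sequences
    exceeding 4 kb are used). ``fixed15kb``/``fixed4kb`` cut consecutive
    non-overlapping windows of 15000/4000 nt, keeping a trailing
    fragment only if it exceeds 4000 nt; ``half``/``quarter`` cut into
    2/4 equal parts (remainder appended to the last part). Fragment ids
    are ``<parent>/<ordinal>`` starting at 1.
    """
    if mode not in FRAGMENT_MODES:
        raise InvalidParameterError(
            f"mode must be one of {FRAGMENT_MODES}, got {mode!r}"
        )
    out: List[SequenceRecord] = []
    for rec in records:
        n = len(rec.sequence)
        if n <= MIN_REFERENCE_LENGTH:
            continue
        if mode in ("fixed15kb", "fixed4kb"):
            width = 15000 if mode == "fixed15kb" else 4000
            pieces = []
            for start in range(0, n, width):
                piece = rec.sequence[start : start + width]
                if len(piece) == width or len(piece) > MIN_REFERENCE_LENGTH:
                    pieces.append(piece)
        else:
            parts = 2 if mode == "half" else 4
            size = n // parts
            pieces = [
                rec.sequence[i * size : (i + 1) * size] for i in range(parts - 1)
            ]
            pieces.append(rec.sequence[(parts - 1) * size :])
        for ordinal, piece in enumerate(pieces, start=1):
            out.append(
                SequenceRecord(f"{rec.id}/{ordinal}", "", piece)
            )
    return out


# --- model persistence -------------------------------------------------

_H5_OPTS = dict(compression="gzip", compression_opts=9, shuffle=True,
                track_times=False)


def save_model(model: H2SOMModel, path: Union[str, Path]) -> None:
    """Serialize a model to a single compressed HDF5 file; prototypes
    are stored as float32."""
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["format_version"] = model.format_version
        f.attrs["k"] = model.k
        f.attrs["s"] = model.s
        f.attrs["r"] = model.r
        f.attrs["normalization"] = model.normalization
        f.attrs["classifier"] = json.dumps(
            {
                "labeling": model.classifier.labeling,
                "alpha": model.classifier.alpha,
                "rule": model.classifier.rule,
                "beta": model.classifier.beta,
                "beam_width": model.classifier.beam_width,
            }
        )
        f.attrs["training"] = json.dumps(vars(model.training))
        f.create_dataset(
            "prototypes", data=model.prototypes.astype(np.float32), **_H5_OPTS
        )
        f.create_dataset(
            "occupancy", data=model.node_labels.occupancy, **_H5_OPTS
        )
        if model.term_stats is not None:
            f.create_dataset(
                "term_totals", data=model.term_stats.term_totals, **_H5_OPTS
            )
        grp = f.create_group("labels")
        for rank in RANKS:
            labels = model.node_labels.for_rank(rank)
            taxa = sorted(set(labels))
            codes = np.array(
                [taxa.index(lab) for lab in labels], dtype=np.int32
            )
            g = grp.create_group(rank)
            g.create_dataset(
                "taxa", data=np.array(taxa, dtype=h5py.string_dtype()),
                track_times=False,
            )
            g.create_dataset("codes", data=codes, **_H5_OPTS)


def load_model(path: Union[str, Path]) -> H2SOMModel:
    """Load a model saved by :func:`save_model`; classifications of the
    restored model match the original (distances to float32 precision)."""
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"no such model file: {path}")
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != FORMAT_VERSION:
                raise ModelFormatError(
                    f"unsupported model format version: expected "
                    f"{FORMAT_VERSION}, found {version}"
                )
            k = int(f.attrs["k"])
            s = int(f.attrs["s"])
            r = int(f.attrs["r"])
            normalization = str(f.attrs["normalization"])
            cls = json.loads(f.attrs["classifier"])
            trn = json.loads(f.attrs["training"])
            prototypes = f["prototypes"][...].astype(np.float64)
            occupancy = f["occupancy"][...]
            term_stats = None
            if "term_totals" in f:
                term_stats = CorpusTermStats(f["term_totals"][...], k)
            labels: Dict[str, List[str]] = {}
            for rank in RANKS:
                g = f["labels"][rank]
                taxa = [t.decode() for t in g["taxa"][...]]
                labels[rank] = [taxa[c] for c in g["codes"][...]]
    except OSError as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    lattice = build_lattice(s, r)
    return H2SOMModel(
        k=k,
        s=s,
        r=r,
        normalization=normalization,
        lattice=lattice,
        prototypes=prototypes,
        node_labels=NodeLabels(labels=labels, occupancy=occupancy),
        classifier=ClassifierConfig(**cls),
        training=TrainingConfig(**trn),
        term_stats=term_stats,
        format_version=FORMAT_VERSION,
    )


# --- result exports ----------------------------------------------------


def write_assignments(
    assignments: Sequence[Assignment], path: Union[str, Path]
) -> None:
    """Write a TSV of per-read assignments: id, one taxon column per
    rank ('REJECTED' where rejected), BMU node, BMU distance."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\t" + "\t".join(RANKS) + "\tbmu_node\tbmu_distance\n"
        )
        for a in assignments:
            cells = [
                "REJECTED" if a.predictions[rank] == REJECT else a.predictions[rank]
                for rank in RANKS
            ]
            fh.write(
                f"{a.read_id}\t" + "\t".join(cells)
                + f"\t{a.node}\t{a.distance:.6g}\n"
            )


def read_assignments_tsv(path: Union[str, Path]) -> List[Assignment]:
    """Parse a TSV written by :func:`write_assignments` back into
    assignments (distances at the written precision)."""
    out: List[Assignment] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[0] != "read_id":
            raise InvalidParameterError(f"{path}: not an assignments TSV")
        for row in reader:
            preds = {
                rank: (REJECT if cell == "REJECTED" else cell)
                for rank, cell in zip(RANKS, row[1 : 1 + len(RANKS)])
            }
            out.append(
                Assignment(row[0], preds, int(row[-2]), float(row[-1]))
            )
    return out


def write_krona_text(
    assignments: Sequence[Assignment], path: Union[str, Path]
) -> None:
    """Write a Krona-importable composition summary: one line per
    distinct assigned lineage path, 'count<TAB>taxon<TAB>taxon...'.
    Reads rejected at the top rank aggregate under 'Unclassified';
    counts sum to the number of reads. Empty input gives an empty file.
    """
    counts: Dict[tuple, int] = {}
    for a in assignments:
        p = tuple(a.lineage_path()) or ("Unclassified",)
        counts[p] = counts.get(p, 0) + 1
    with open(path, "w") as fh:
        for p in sorted(counts):
            fh.write("\t".join([str(counts[p]), *p]) + "\n")
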