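"""Multi-type bipartite association networks and their on-disk edge-list format.

The central container is :class:`MultiTypeNetwork`: a binary tensor of shape
``(n_diseases, n_mirnas, n_types)`` whose entry ``(i, u, k)`` is 1 iff disease
``i`` and miRNA ``u`` have a known association of type ``k``, together with the
ordered identifier vocabularies for each axis.

The on-disk representation is a UTF-8 tab-separated edge list with a mandatory
header row ``mirna  disease  type``, one row per known (miRNA, disease, type)
triple.  Optional ``#``-prefixed metadata lines above the header record the
full vocabularies so that entities without any association (and the exact axis
ordering) survive a write/load round trip; files without metadata are read
with first-appearance ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four association-evidence categories of the HMDD v2.0 classification,
#: in canonical order: direct miRNA-target interaction, circulating miRNA,
#: epigenetic and genetic evidence.
CANONICAL_TYPES: tuple[str, ...] = ("target", "circulation", "epigenetics", "genetics")

REQUIRED_COLUMNS = ("mirna", "disease", "type")


class DataError(ValueError):
    """Raised for malformed or inconsistent association data."""


@dataclass(frozen=True)
class AssociationRecord:
    """One known (miRNA, disease, type) triple."""

    mirna: str
    disease: str
    assoc_type: str


@dataclass
class MultiTypeNetwork:
    """Observed multi-type miRNA-disease association tensor with vocabularies.

    Parameters
    ----------
    disease_ids, mirna_ids, type_ids
        Ordered, duplicate-free identifier lists for the three tensor axes.
    tensor
        Binary array of shape ``(len(disease_ids), len(mirna_ids),
        len(type_ids))``; stored as ``int8``.
    """

    disease_ids: list[str]
    mirna_ids: list[str]
    type_ids: list[str]
    tensor: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.disease_ids = list(self.disease_ids)
        self.mirna_ids = list(self.mirna_ids)
        self.type_ids = list(self.type_ids)
        for name, ids in (
            ("disease_ids", self.disease_ids),
            ("mirna_ids", self.mirna_ids),
            ("type_ids", self.type_ids),
        ):
            if len(set(ids)) != len(ids):
                raise DataError(f"{name} contains duplicate labels")
        tensor = np.asarray(self.tensor)
        expected = (len(self.disease_ids), len(self.mirna_ids), len(self.type_ids))
        if tensor.shape != expected:
            raise DataError(
                f"tensor shape {tensor.shape} does not match vocabulary sizes {expected}"
            )
        if not np.isin(tensor, (0, 1)).all():
            raise DataError("tensor entries must be exactly 0 or 1")
        self.tensor = tensor.astype(np.int8, copy=False)
        silent = self.silent_mirnas()
        if silent:
            logger.info(
                "%d miRNA(s) have no known association and carry no training "
                "signal: %s",
                len(silent),
                ", ".join(silent[:5]) + ("..." if len(silent) > 5 else ""),
            )

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_types(self) -> int:
        return len(self.type_ids)

    @property
    def n_associations(self) -> int:
        return int(self.tensor.sum())

    def silent_mirnas(self) -> list[str]:
        """miRNAs whose entire n x t slice is zero (no training signal)."""
        mask = self.tensor.sum(axis=(0, 2)) == 0
        return [m for m, flag in zip(self.mirna_ids, mask) if flag]

    def disease_index(self, disease: str) -> int:
        try:
            return self.disease_ids.index(disease)
        except ValueError:
            raise DataError(f"unknown disease label: {disease!r}") from None

    def mirna_index(self, mirna: str) -> int:
        try:
            return self.mirna_ids.index(mirna)
        except ValueError:
            raise DataError(f"unknown miRNA label: {mirna!r}") from None

    def type_index(self, assoc_type: str) -> int:
        try:
            return self.type_ids.index(assoc_type)
        except ValueError:
            raise DataError(f"unknown association type label: {assoc_type!r}") from None

    def triple_index(self, rec: AssociationRecord) -> tuple[int, int, int]:
        """Tensor index (i, u, k) of an association record."""
        return (
            self.disease_index(rec.disease),
            self.mirna_index(rec.mirna),
            self.type_index(rec.assoc_type),
        )

    def records(self) -> list[AssociationRecord]:
        """All known triples in (disease, mirna, type) index order."""
        out = []
        for i, u, k in np.argwhere(self.tensor == 1):
            out.append(
                AssociationRecord(
                    mirna=self.mirna_ids[u],
                    disease=self.disease_ids[i],
                    assoc_type=self.type_ids[k],
                )
            )
        return out

    def copy(self) -> "MultiTypeNetwork":
        return MultiTypeNetwork(
            list(self.disease_ids),
            list(self.mirna_ids),
            list(self.type_ids),
            self.tensor.copy(),
        )


@dataclass(frozen=True)
class NetworkSummary:
    """Per-type association counts and densities of a network."""

    counts: dict[str, int]
    densities: dict[str, float]
    total: int
    overall_density: float


def summarize(net: MultiTypeNetwork) -> NetworkSummary:
    """Count known associations per type; the counts sum to the tensor total."""
    per_type = net.tensor.sum(axis=(0, 1))
    cells = net.n_diseases * net.n_mirnas
    counts = {t: int(c) for t, c in zip(net.type_ids, per_type)}
    densities = {t: (c / cells if cells else 0.0) for t, c in counts.items()}
    total = int(per_type.sum())
    return NetworkSummary(
        counts=counts,
        densities=densities,
        total=total,
        overall_density=total / (cells * net.n_types) if cells else 0.0,
    )


def _read_metadata(path: Path) -> dict[str, list[str]]:
    meta: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip("\n").strip()
            for key in ("types", "diseases", "mirnas"):
                prefix = key + ":"
                if body.startswith(prefix):
                    payload = body[len(prefix):].lstrip("\t").lstrip()
                    meta[key] = payload.split("\t") if payload else []
    return meta


def load_association_table(
    path: str | Path,
    type_vocabulary: Sequence[str] | None = None,
    delimiter: str = "\t",
) -> MultiTypeNetwork:
    """Read a delimited edge list into a :class:`MultiTypeNetwork`.

    The file must have a header row with columns ``mirna``, ``disease`` and
    ``type``.  Duplicate rows collapse to a single 1 (set semantics).  When a
    ``type_vocabulary`` is supplied, any row with a type outside it is
    rejected with its row number.  Without one, the canonical four HMDD
    labels are used whenever every observed type belongs to them; otherwise
    types are taken in first-appearance order.  Disease and miRNA orderings
    are first-appearance order unless the file carries ``#`` metadata lines
    written by :func:`write_association_table`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise DataError(f"empty association table: {path}") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(
            f"{path}: missing required column(s) {missing}; header row with "
            f"columns {list(REQUIRED_COLUMNS)} is mandatory"
        )
    df = df[list(REQUIRED_COLUMNS)]

    meta = _read_metadata(path)

    if type_vocabulary is not None:
        type_ids = list(type_vocabulary)
    elif "types" in meta:
        type_ids = meta["types"]
    else:
        observed: list[str] = []
        for t in df["type"]:
            if t not in observed:
                observed.append(t)
        if set(observed) <= set(CANONICAL_TYPES):
            type_ids = list(CANONICAL_TYPES)
        else:
            type_ids = observed

    known_types = set(type_ids)
    for row_number, t in enumerate(df["type"], start=2):  # 1-based + header
        if t not in known_types:
            raise DataError(
                f"{path} row {row_number}: unknown association type {t!r}; "
                f"allowed types: {type_ids}"
            )

    if "diseases" in meta:
        disease_ids = meta["diseases"]
    else:
        disease_ids = list(dict.fromkeys(df["disease"]))
    if "mirnas" in meta:
        mirna_ids = meta["mirnas"]
    else:
        mirna_ids = list(dict.fromkeys(df["mirna"]))

    n_rows = len(df)
    dedup = df.drop_duplicates()
    if len(dedup) < n_rows:
        logger.info("collapsed %d duplicate association row(s)", n_rows - len(dedup))

    d_idx = {d: i for i, d in enumerate(disease_ids)}
    m_idx = {m: i for i, m in enumerate(mirna_ids)}
    t_idx = {t: i for i, t in enumerate(type_ids)}
    tensor = np.zeros((len(disease_ids), len(mirna_ids), len(type_ids)), dtype=np.int8)
    for mirna, disease, assoc_type in dedup.itertuples(index=False):
        try:
            tensor[d_idx[disease], m_idx[mirna], t_idx[assoc_type]] = 1
        except KeyError as exc:
            raise DataError(
                f"{path}: label {exc.args[0]!r} not present in file metadata "
                "vocabularies"
            ) from None
    return MultiTypeNetwork(disease_ids, mirna_ids, type_ids, tensor)


def write_association_table(
    net: MultiTypeNetwork,
    path: str | Path,
    delimiter: str = "\t",
    metadata: bool = True,
) -> Path:
    """Write a network as a tab-separated edge list.

    With ``metadata=True`` (default) the vocabularies are stored in
    ``#``-comment lines so that ``load(write(net))`` is the identity on both
    tensor and vocabularies even for entities with no association.
    """
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            if metadata:
                fh.write("# mirbm multi-type association edge list\n")
                fh.write("# types:\t" + "\t".join(net.type_ids) + "\n")
                fh.write("# diseases:\t" + "\t".join(net.disease_ids) + "\n")
                fh.write("# mirnas:\t" + "\t".join(net.mirna_ids) + "\n")
            fh.write(delimiter.join(REQUIRED_COLUMNS) + "\n")
            for i, u, k in np.argwhere(net.tensor == 1):
                fh.write(
                    delimiter.join(
                        (net.mirna_ids[u], net.disease_ids[i], net.type_ids[k])
                    )
                    + "\n"
                )
    except OSError as exc:
        raise DataError(f"cannot write association table to {path}: {exc}") from exc
    return path


def network_from_records(
    records: Sequence[AssociationRecord],
    disease_ids: Sequence[str] | None = None,
    mirna_ids: Sequence[str] | None = None,
    type_ids: Sequence[str] | None = None,
) -> MultiTypeNetwork:
    """Build a network from triples, deriving vocabularies in first-appearance
    order where not given."""
    if type_ids is None:
        seen = list(dict.fromkeys(r.assoc_type for r in records))
        type_ids = list(CANONICAL_TYPES) if set(seen) <= set(CANONICAL_TYPES) else seen
    if disease_ids is None:
        disease_ids = list(dict.fromkeys(r.disease for r in records))
    if mirna_ids is None:
        mirna_ids = list(dict.fromkeys(r.mirna for r in records))
    net = MultiTypeNetwork(
        list(disease_ids),
        list(mirna_ids),
        list(type_ids),
        np.zeros((len(disease_ids), len(mirna_ids), len(type_ids)), dtype=np.int8),
    )
    for rec in records:
        i, u, k = net.triple_index(rec)
        net.tensor[i, u, k] = 1
    return net
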