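"""Weighted brain-network containers, file formats, and preprocessing filters.

A connectome here is an undirected, positively weighted graph over parcellated
gray-matter regions: nodes are atlas ROIs (tagged left / right / brainstem),
edge weights are normalized streamline volumes from deterministic tractography.
This module owns the on-disk dialects (plain-text adjacency matrix, node
metadata table, cohort manifest), validation of the graph invariants, and the
two preprocessing steps applied before curvature is computed: normalization by
whole-brain white-matter volume and removal of cross-hemisphere edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("braincurv")

#: Behavioral change measures, in canonical order. VABS-SS and EOW changes are
#: follow-up minus baseline (higher = more improvement); CGI-I is the 6-month
#: improvement rating used directly (lower = more improvement).
MEASURES = ("VABS-SS", "EOW", "CGI-I")

#: Manifest column holding each measure.
MEASURE_COLUMNS = {"VABS-SS": "d_vabs", "EOW": "d_eow", "CGI-I": "cgi_i"}

HEMISPHERES = ("left", "right", "none")

#: Asymmetry beyond this (relative to the largest weight) is rejected;
#: below it the matrix is symmetrized by averaging.
ASYMMETRY_TOL = 1e-8


class ConnectomeError(ValueError):
    """Invalid network, matrix file, or cohort manifest."""


@dataclass(frozen=True)
class BrainNetwork:
    """Symmetric non-negative weighted graph with hemisphere-tagged nodes.

    Parameters
    ----------
    node_ids
        Unique region identifiers, in matrix order.
    node_names
        Human-readable region label per node.
    hemisphere
        ``"left"``, ``"right"`` or ``"none"`` (brainstem) per node.
    weights
        Square symmetric matrix of non-negative edge weights with zero
        diagonal; ``weights[i, j] == 0`` means no edge.
    """

    node_ids: tuple[str, ...]
    node_names: tuple[str, ...]
    hemisphere: tuple[str, ...]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if w.ndim != 2 or w.shape != (n, n):
            raise ConnectomeError(
                f"weights must be {n}x{n}, got shape {w.shape}"
            )
        if len(self.node_names) != n or len(self.hemisphere) != n:
            raise ConnectomeError("metadata length does not match node count")
        if len(set(self.node_ids)) != n:
            raise ConnectomeError("node_ids are not unique")
        bad = set(self.hemisphere) - set(HEMISPHERES)
        if bad:
            raise ConnectomeError(f"unknown hemisphere labels: {sorted(bad)}")
        if np.isnan(w).any():
            raise ConnectomeError("weights contain NaN")
        if (w < 0).any():
            i, j = np.argwhere(w < 0)[0]
            raise ConnectomeError(f"negative weight at ({i}, {j}): {w[i, j]}")
        if not np.array_equal(w, w.T):
            raise ConnectomeError("weights matrix is not symmetric")
        if np.diag(w).any():
            raise ConnectomeError("weights diagonal is not zero")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edges(self) -> list[tuple[int, int]]:
        """Positive-weight node pairs as (i, j) with i < j, sorted."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.weights[iu, ju] > 0
        return list(zip(iu[mask].tolist(), ju[mask].tolist()))

    def with_weights(self, weights: np.ndarray) -> "BrainNetwork":
        """Same nodes, new weight matrix (revalidated)."""
        return replace(self, weights=weights)


@dataclass(frozen=True)
class CohortRecord:
    """One subject's longitudinal pair of networks plus behavioral changes."""

    subject_id: str
    baseline: BrainNetwork
    followup: BrainNetwork
    behavior: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.baseline.node_ids != self.followup.node_ids:
            raise ConnectomeError(
                f"subject {self.subject_id}: baseline and follow-up node sets differ"
            )
        missing = [m for m in MEASURES if m not in self.behavior]
        if missing:
            raise ConnectomeError(
                f"subject {self.subject_id}: missing behavioral measures {missing}"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _load_matrix(matrix_path: str | Path) -> np.ndarray:
    path = Path(matrix_path)
    try:
        # loadtxt handles both whitespace- and comma-delimited dialects
        text = path.read_text()
    except OSError as exc:
        raise ConnectomeError(f"cannot read matrix file {path}: {exc}") from exc
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        w = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ConnectomeError(f"malformed matrix file {path}: {exc}") from exc
    if w.shape[0] != w.shape[1]:
        raise ConnectomeError(
            f"{path}: matrix is {w.shape[0]}x{w.shape[1]}, expected square"
        )
    return w


def read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    """Read the node-metadata table (tab-delimited: id, name, hemisphere)."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"id", "name", "hemisphere"}
    if not required.issubset(meta.columns):
        raise ConnectomeError(
            f"{metadata_path}: metadata needs columns {sorted(required)}"
        )
    return meta


def read_network(matrix_path: str | Path, metadata_path: str | Path) -> BrainNetwork:
    """Load a connectome from an adjacency-matrix file and a metadata table.

    The matrix must be square, numeric, non-negative and symmetric (asymmetry
    below ``ASYMMETRY_TOL`` relative to the largest weight is averaged away;
    anything larger is rejected as corrupted input). Self-loops — intra-ROI
    streamline volume on the diagonal — are dropped with a warning: the
    random-walk measure is defined over *neighbors*, so diagonal mass has no
    place in the model.
    """
    w = _load_matrix(matrix_path)
    meta = read_metadata(metadata_path)
    if len(meta) != w.shape[0]:
        raise ConnectomeError(
            f"{metadata_path}: {len(meta)} metadata rows for a "
            f"{w.shape[0]}x{w.shape[0]} matrix"
        )
    if np.isnan(w).any():
        i, j = np.argwhere(np.isnan(w))[0]
        raise ConnectomeError(f"{matrix_path}: NaN entry at ({i}, {j})")
    if (w < 0).any():
        i, j = np.argwhere(w < 0)[0]
        raise ConnectomeError(
            f"{matrix_path}: negative weight {w[i, j]} at ({i}, {j})"
        )
    asym = np.abs(w - w.T).max()
    scale = max(w.max(), 1.0)
    if asym > ASYMMETRY_TOL * scale:
        raise ConnectomeError(
            f"{matrix_path}: asymmetry {asym:.3g} exceeds tolerance"
        )
    if asym > 0:
        w = (w + w.T) / 2.0
    if np.diag(w).any():
        logger.warning(
            "%s: dropping %d self-loop(s) on the diagonal",
            matrix_path,
            int(np.count_nonzero(np.diag(w))),
        )
        np.fill_diagonal(w, 0.0)
    return BrainNetwork(
        node_ids=tuple(meta["id"]),
        node_names=tuple(meta["name"]),
        hemisphere=tuple(meta["hemisphere"]),
        weights=w,
    )


def write_network(
    network: BrainNetwork,
    matrix_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write the adjacency matrix (and optionally metadata) as plain text.

    Weights are printed with ``%.17g`` so float64 values round-trip exactly.
    """
    np.savetxt(matrix_path, network.weights, fmt="%.17g", delimiter="\t")
    if metadata_path is not None:
        write_metadata(network, metadata_path)


def write_metadata(network: BrainNetwork, metadata_path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": network.node_ids,
            "name": network.node_names,
            "hemisphere": network.hemisphere,
        }
    ).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preprocessing filters
# ---------------------------------------------------------------------------

def normalize_edge_weights(network: BrainNetwork, total_volume: float) -> BrainNetwork:
    """Divide every edge weight by whole-brain white-matter volume.

    Edge volumes from tractography are normalized per subject so that weights
    are comparable across participants and timepoints. The zero pattern is
    unchanged. Inputs that arrive pre-normalized can skip this step.
    """
    if not total_volume > 0:
        raise ConnectomeError(f"total_volume must be positive, got {total_volume}")
    return network.with_weights(network.weights / float(total_volume))


def remove_cross_hemisphere_edges(
    network: BrainNetwork, keep_brainstem: bool = True
) -> BrainNetwork:
    """Zero out every edge joining the left and right hemispheres.

    Low-angular-resolution DTI resolves interhemispheric streamlines poorly,
    so left-right edges are removed before curvature is computed. Edges
    touching a node with no hemisphere (the brainstem) are retained when
    ``keep_brainstem`` is true (the default) and removed otherwise.
    Idempotent; never touches intra-hemisphere edges.
    """
    hemi = np.asarray(network.hemisphere)
    left = hemi == "left"
    right = hemi == "right"
    none = hemi == "none"
    drop = np.outer(left, right) | np.outer(right, left)
    if not keep_brainstem:
        drop |= np.outer(none, ~none) | np.outer(~none, none) | np.outer(none, none)
    w = network.weights.copy()
    w[drop] = 0.0
    return network.with_weights(w)


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "subject_id",
    "baseline_path",
    "followup_path",
    "d_vabs",
    "d_eow",
    "cgi_i",
)

#: Node metadata file assumed to sit beside the manifest when neither a
#: metadata_path column nor an explicit argument names one.
DEFAULT_METADATA_NAME = "nodes.tsv"


def read_cohort(
    manifest_path: str | Path, metadata_path: str | Path | None = None
) -> list[CohortRecord]:
    """Load a longitudinal cohort from a manifest table.

    The manifest is tab- or comma-delimited with one row per subject:
    subject id, baseline/follow-up matrix paths, and the three behavioral
    change scores. Node metadata (shared by the whole cohort) comes from an
    optional ``metadata_path`` column, the ``metadata_path`` argument, or a
    ``nodes.tsv`` beside the manifest, in that order. Relative paths are
    resolved against the manifest's directory. All subjects must share an
    identical node ordering.
    """
    manifest_path = Path(manifest_path)
    sep = "\t" if "\t" in manifest_path.read_text().splitlines()[0] else ","
    table = pd.read_csv(manifest_path, sep=sep)
    missing_cols = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ConnectomeError(
            f"{manifest_path}: manifest missing columns {sorted(missing_cols)}"
        )
    if table[["d_vabs", "d_eow", "cgi_i"]].isna().any().any():
        raise ConnectomeError(f"{manifest_path}: missing behavioral score(s)")
    base_dir = manifest_path.parent

    def resolve(p: str | Path) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base_dir / path

    records: list[CohortRecord] = []
    reference: tuple[str, ...] | None = None
    for row in table.itertuples(index=False):
        if "metadata_path" in table.columns:
            meta_path = resolve(row.metadata_path)
        elif metadata_path is not None:
            meta_path = Path(metadata_path)
        else:
            meta_path = base_dir / DEFAULT_METADATA_NAME
        baseline = read_network(resolve(row.baseline_path), meta_path)
        followup = read_network(resolve(row.followup_path), meta_path)
        record = CohortRecord(
            subject_id=str(row.subject_id),
            baseline=baseline,
            followup=followup,
            behavior={
                "VABS-SS": float(row.d_vabs),
                "EOW": float(row.d_eow),
                "CGI-I": float(row.cgi_i),
            },
        )
        if reference is None:
            reference = baseline.node_ids
        elif baseline.node_ids != reference:
            raise ConnectomeError(
                f"subject {record.subject_id}: node set differs from the "
                "first subject's"
            )
        records.append(record)
    return records


def write_cohort_manifest(
    manifest_path: str | Path, rows: Sequence[Mapping[str, object]]
) -> None:
    """Write a cohort manifest (tab-delimited, canonical columns first)."""
    frame = pd.DataFrame(list(rows))
    ordered = [c for c in MANIFEST_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in ordered]
    frame[ordered + extra].to_csv(manifest_path, sep="\t", index=False)
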