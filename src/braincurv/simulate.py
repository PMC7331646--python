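"""Synthetic longitudinal connectome cohorts with known ground truth.

The generator emulates the statistical shape of a small pre/post DTI study:
a cohort of subjects, each with a baseline and follow-up 83-region
connectome (41 regions per hemisphere plus the brainstem), symmetric
non-negative weights, and three behavioral change scores. Subjects share
one edge support — connectomes built from a fixed atlas parcellation
overlap heavily in topology — while weights vary per subject, drawn
log-normal to mimic the heavy-tailed, strictly positive distribution of
normalized streamline volumes.

A per-subject latent improvement factor L ~ N(0,1) couples everything:
each planted intra-hemisphere edge — together with its triangle support,
the edges joining its endpoints to their common neighbors — changes
weight by exp(effect_size * L) between timepoints, and the three
behavioral scores are noisy linear functions of L with the direction
conventions of the instruments (VABS-SS and EOW increase with
improvement, CGI-I decreases). Strengthening a pathway *with* its
triangles is what raises Ollivier-Ricci curvature: feedback triangles
are the geometry behind the curvature-robustness link, whereas inflating
one edge in isolation concentrates each endpoint's walk measure on the
other endpoint and lowers curvature. Recovery of the planted edges by
the analysis pipeline is an end-to-end test with a known answer: the
effect enters through edge weights, and curvature must transduce it,
exactly the mechanism the analysis probes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .io import (
    BrainNetwork,
    CohortRecord,
    write_cohort_manifest,
    write_metadata,
    write_network,
)
from .longitudinal import CorrelationRow

#: Behavioral score scales (mean, sd) of the change measures in the kind of
#: cohort emulated: Vineland socialization delta 3.37 +/- 6.71, expressive
#: vocabulary delta 4.95 +/- 6.34, CGI improvement rating 2.79 +/- 1.82.
BEHAVIOR_SCALES = {
    "VABS-SS": (3.37, 6.71),
    "EOW": (4.95, 6.34),
    "CGI-I": (2.79, 1.82),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a simulated cohort.

    ``n_nodes`` splits into two equal hemispheres plus a brainstem remainder
    (83 -> 41 left, 41 right, 1 brainstem). ``edge_density`` is the fraction
    of intra-hemisphere pairs connected; a small ``cross_hemisphere_density``
    adds left-right edges so the preprocessing filter has something to
    remove. A cohort-level weight template is drawn
    log-normal(``weight_mu``, ``weight_sigma``); each subject's baseline
    deviates from it by multiplicative log-normal noise of scale
    ``subject_weight_sd`` (the same anatomical connection varies across
    individuals but keeps its character). Follow-up weights carry
    multiplicative log-normal noise of scale ``weight_noise_sd`` on every
    edge, and planted edges additionally scale by exp(``effect_size`` * L).
    ``noise_sd`` is the behavioral noise in units of the latent factor's
    standard deviation.
    """

    n_subjects: int = 19
    n_nodes: int = 83
    edge_density: float = 0.3
    cross_hemisphere_density: float = 0.05
    weight_mu: float = -4.0
    weight_sigma: float = 1.0
    subject_weight_sd: float = 0.3
    n_planted: int = 3
    planted_edges: tuple[tuple[int, int], ...] | None = None
    effect_size: float = 0.5
    noise_sd: float = 0.5
    weight_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.edge_density <= 1:
            raise ValueError(f"edge_density must be in (0, 1], got {self.edge_density}")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.n_nodes < 4:
            raise ValueError("need at least 4 nodes")

    @property
    def n_per_hemisphere(self) -> int:
        return self.n_nodes // 2

    @property
    def hemisphere_labels(self) -> tuple[str, ...]:
        per = self.n_per_hemisphere
        rest = self.n_nodes - 2 * per
        return ("left",) * per + ("right",) * per + ("none",) * rest

    def node_metadata(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        per = self.n_per_hemisphere
        ids, names = [], []
        for i, hemi in enumerate(self.hemisphere_labels):
            if hemi == "left":
                ids.append(f"L{i + 1:02d}")
                names.append(f"left_region_{i + 1:02d}")
            elif hemi == "right":
                ids.append(f"R{i - per + 1:02d}")
                names.append(f"right_region_{i - per + 1:02d}")
            else:
                ids.append(f"B{i - 2 * per + 1:02d}")
                names.append("brainstem")
        return tuple(ids), tuple(names)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: which edges, how strongly, and whose curvature moves.

    ``affected_nodes`` lists every node whose random-walk measure responds
    to the planted perturbation (the planted endpoints plus their common
    neighbors carrying the triangle-support edges); any edge touching one
    of these nodes legitimately changes curvature.
    """

    planted_edges: tuple[tuple[int, int], ...]
    latent_improvement: np.ndarray = field(repr=False)
    realized_weight_changes: np.ndarray = field(repr=False)  # (n_subjects, n_planted)
    affected_nodes: tuple[int, ...] | None = None


# ---------------------------------------------------------------------------
# Support (topology) sampling
# ---------------------------------------------------------------------------

def _hemisphere_connected(support: np.ndarray, nodes: np.ndarray) -> bool:
    sub = support[np.ix_(nodes, nodes)]
    n_comp, _ = connected_components(sparse.csr_matrix(sub), directed=False)
    return n_comp == 1


def _sample_support(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean adjacency: connected within each hemisphere, sparse across."""
    hemi = np.asarray(config.hemisphere_labels)
    n = config.n_nodes
    left = np.flatnonzero(hemi == "left")
    right = np.flatnonzero(hemi == "right")
    stem = np.flatnonzero(hemi == "none")
    for _ in range(100):
        support = np.zeros((n, n), dtype=bool)
        iu, ju = np.triu_indices(n, k=1)
        same_left = np.isin(iu, left) & np.isin(ju, left)
        same_right = np.isin(iu, right) & np.isin(ju, right)
        cross = (np.isin(iu, left) & np.isin(ju, right)) | (
            np.isin(iu, right) & np.isin(ju, left)
        )
        stem_pair = np.isin(iu, stem) | np.isin(ju, stem)
        prob = np.zeros(iu.shape)
        prob[same_left | same_right] = config.edge_density
        prob[cross] = config.cross_hemisphere_density
        prob[stem_pair] = config.edge_density
        keep = rng.random(iu.shape) < prob
        support[iu[keep], ju[keep]] = True
        support |= support.T
        if (
            (left.size == 0 or _hemisphere_connected(support, left))
            and (right.size == 0 or _hemisphere_connected(support, right))
            and (stem.size == 0 or (support[stem].sum(axis=1) > 0).all())
        ):
            return support
    raise ValueError(
        f"edge_density {config.edge_density} too low to connect a hemisphere "
        "after 100 attempts"
    )


def _weights_on_support(
    support: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    n = support.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = support[iu, ju]
    w = np.zeros((n, n))
    vals = rng.lognormal(config.weight_mu, config.weight_sigma, mask.sum())
    w[iu[mask], ju[mask]] = vals
    return w + w.T


def _network(config: SyntheticConfig, weights: np.ndarray) -> BrainNetwork:
    ids, names = config.node_metadata()
    return BrainNetwork(
        node_ids=ids,
        node_names=names,
        hemisphere=config.hemisphere_labels,
        weights=weights,
    )


def generate_baseline(config: SyntheticConfig, seed: int | None = None) -> BrainNetwork:
    """One random baseline connectome (own topology and weights)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    support = _sample_support(config, rng)
    return _network(config, _weights_on_support(support, config, rng))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _pick_planted(
    config: SyntheticConfig, support: np.ndarray, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    if config.planted_edges is not None:
        planted = tuple(tuple(sorted(e)) for e in config.planted_edges)
        hemi = config.hemisphere_labels
        for i, j in planted:
            if not support[i, j]:
                raise ValueError(f"planted edge ({i}, {j}) not in the sampled support")
            if hemi[i] != hemi[j] or hemi[i] == "none":
                raise ValueError(f"planted edge ({i}, {j}) is not intra-hemisphere")
        return planted
    hemi = np.asarray(config.hemisphere_labels)
    iu, ju = np.triu_indices(config.n_nodes, k=1)
    ok = (
        support[iu, ju]
        & (hemi[iu] == hemi[ju])
        & (hemi[iu] != "none")
    )
    candidates = list(zip(iu[ok].tolist(), ju[ok].tolist()))
    # Planted edges need triangle support (a common neighbor) to carry the
    # effect, and pairwise-distinct endpoints so their signals do not
    # overlap through shared node measures.
    rng.shuffle(candidates)
    supported = [
        (i, j) for i, j in candidates if (support[i] & support[j]).any()
    ]
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    for i, j in supported:
        if i in used or j in used:
            continue
        chosen.append((i, j))
        used.update((i, j))
        if len(chosen) == config.n_planted:
            break
    # Sparse supports may not offer enough endpoint-disjoint candidates;
    # fall back to letting planted edges share endpoints.
    if len(chosen) < config.n_planted:
        for edge in supported:
            if edge not in chosen:
                chosen.append(edge)
            if len(chosen) == config.n_planted:
                break
    if len(chosen) < config.n_planted:
        raise ValueError("support too sparse to place the requested planted edges")
    return tuple(sorted(chosen))


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[CohortRecord], GroundTruth]:
    """Simulate a full cohort; a pure function of the config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    support = _sample_support(config, rng)
    planted = _pick_planted(config, support, rng)
    latent = rng.standard_normal(config.n_subjects)
    scale = np.sqrt(1.0 + config.noise_sd**2)

    # The planted perturbation scales each planted edge and its triangle
    # support: the edges from both endpoints to every common neighbor.
    planted_cells: list[tuple[int, int]] = []
    affected: set[int] = set()
    for i, j in planted:
        planted_cells.append((i, j))
        affected.update((i, j))
        for c in np.flatnonzero(support[i] & support[j]):
            planted_cells.append(tuple(sorted((i, int(c)))))
            planted_cells.append(tuple(sorted((j, int(c)))))
            affected.add(int(c))

    iu, ju = np.triu_indices(config.n_nodes, k=1)
    mask = support[iu, ju]
    template = _weights_on_support(support, config, rng)
    records: list[CohortRecord] = []
    realized = np.zeros((config.n_subjects, len(planted)))
    for s in range(config.n_subjects):
        subj_dev = rng.normal(0.0, config.subject_weight_sd, int(mask.sum())) \
            if config.subject_weight_sd > 0 else np.zeros(int(mask.sum()))
        base_w = np.zeros_like(template)
        base_w[iu[mask], ju[mask]] = template[iu[mask], ju[mask]] * np.exp(subj_dev)
        base_w = base_w + base_w.T
        noise = rng.normal(0.0, config.weight_noise_sd, int(mask.sum())) \
            if config.weight_noise_sd > 0 else np.zeros(int(mask.sum()))
        follow_w = np.zeros_like(base_w)
        follow_w[iu[mask], ju[mask]] = base_w[iu[mask], ju[mask]] * np.exp(noise)
        follow_w = follow_w + follow_w.T
        multiplier = np.exp(config.effect_size * latent[s])
        for i, j in set(planted_cells):
            follow_w[i, j] *= multiplier
            follow_w[j, i] = follow_w[i, j]
        for e_idx, (i, j) in enumerate(planted):
            realized[s, e_idx] = follow_w[i, j] / base_w[i, j]
        behavior = {}
        for measure, (mean, sd) in BEHAVIOR_SCALES.items():
            z = (latent[s] + config.noise_sd * rng.standard_normal()) / scale
            sign = -1.0 if measure == "CGI-I" else 1.0
            behavior[measure] = mean + sign * sd * z
        records.append(
            CohortRecord(
                subject_id=f"sub-{s + 1:02d}",
                baseline=_network(config, base_w),
                followup=_network(config, follow_w),
                behavior=behavior,
            )
        )
    truth = GroundTruth(
        planted_edges=planted,
        latent_improvement=latent,
        realized_weight_changes=realized,
        affected_nodes=tuple(sorted(affected)),
    )
    return records, truth


# ---------------------------------------------------------------------------
# On-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(
    records: Sequence[CohortRecord],
    truth: GroundTruth,
    out_dir: str | Path,
) -> Path:
    """Write matrices, metadata, manifest and ground-truth sidecar; returns
    the manifest path, ready for the analyze stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_metadata(records[0].baseline, out / "nodes.tsv")
    rows = []
    for rec in records:
        base = f"{rec.subject_id}_baseline.txt"
        follow = f"{rec.subject_id}_followup.txt"
        write_network(rec.baseline, out / base)
        write_network(rec.followup, out / follow)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "baseline_path": base,
                "followup_path": follow,
                "d_vabs": repr(float(rec.behavior["VABS-SS"])),
                "d_eow": repr(float(rec.behavior["EOW"])),
                "cgi_i": repr(float(rec.behavior["CGI-I"])),
            }
        )
    manifest = out / "manifest.tsv"
    write_cohort_manifest(manifest, rows)
    node_ids = records[0].baseline.node_ids
    affected = truth.affected_nodes or tuple(
        sorted({n for e in truth.planted_edges for n in e})
    )
    sidecar = {
        "planted_edges": [
            [node_ids[i], node_ids[j]] for i, j in truth.planted_edges
        ],
        "planted_edge_indices": [list(e) for e in truth.planted_edges],
        "affected_nodes": list(affected),
        "affected_node_labels": [node_ids[i] for i in affected],
        "latent_improvement": truth.latent_improvement.tolist(),
        "realized_weight_changes": truth.realized_weight_changes.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return manifest


def read_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_edges=tuple(tuple(e) for e in data["planted_edge_indices"]),
        latent_improvement=np.array(data["latent_improvement"]),
        realized_weight_changes=np.array(data["realized_weight_changes"]),
        affected_nodes=tuple(data["affected_nodes"])
        if "affected_nodes" in data else None,
    )


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    """How well the pipeline recovered the planted effects (edge units).

    The planted perturbation moves the random-walk measure of every
    affected node (planted endpoints and their triangle-support
    neighbors), so edges incident to those nodes genuinely change
    curvature too; such units are tallied as ``n_selected_adjacent``
    rather than as false positives. ``n_false_positive`` counts selected
    edges touching no affected node; ``n_selected_nonplanted`` is the
    undiscriminating total.
    """

    sensitivity: float
    n_planted: int
    n_planted_selected: int
    n_selected_adjacent: int
    n_false_positive: int
    n_selected_nonplanted: int
    n_edge_units: int


def recovery_study(
    base_config: SyntheticConfig,
    run_config,
    n_seeds: int,
) -> dict:
    """Repeat simulate -> analyze -> recover over consecutive seeds.

    Returns per-seed sensitivities and false-positive counts, plus the
    Spearman-sign tallies of selected planted units per behavioral measure
    (the direction fingerprint: robustness gain tracks VABS-SS/EOW
    positively and the CGI-I improvement rating negatively).
    """
    import dataclasses

    from .longitudinal import run_analysis

    sensitivities: list[float] = []
    false_positives: list[int] = []
    signs: dict[str, list[float]] = {m: [] for m in BEHAVIOR_SCALES}
    for offset in range(n_seeds):
        config = dataclasses.replace(base_config, seed=base_config.seed + offset)
        records, truth = generate_cohort(config)
        rows = run_analysis(records, run_config)
        report = recovery_report(truth, rows)
        sensitivities.append(report.sensitivity)
        false_positives.append(report.n_false_positive)
        planted = {tuple(sorted(e)) for e in truth.planted_edges}
        for row in rows:
            if (
                row.unit_type == "edge"
                and row.selected
                and tuple(sorted(row.unit_key)) in planted
            ):
                for m in BEHAVIOR_SCALES:
                    signs[m].append(float(np.sign(row.r[m])))
    return {
        "sensitivities": sensitivities,
        "false_positives": false_positives,
        "selected_planted_signs": signs,
    }


def recovery_report(
    truth: GroundTruth, results: Sequence[CorrelationRow]
) -> RecoveryReport:
    planted = {tuple(sorted(e)) for e in truth.planted_edges}
    endpoints = (
        set(truth.affected_nodes)
        if truth.affected_nodes is not None
        else {n for e in planted for n in e}
    )
    edge_rows = [r for r in results if r.unit_type == "edge"]
    if not planted:
        raise ValueError("ground truth contains no planted edges")
    n_sel_planted = 0
    n_sel_adjacent = 0
    n_false = 0
    for row in edge_rows:
        key = tuple(sorted(row.unit_key))
        if key in planted:
            n_sel_planted += int(row.selected)
        elif row.selected and (key[0] in endpoints or key[1] in endpoints):
            n_sel_adjacent += 1
        elif row.selected:
            n_false += 1
    return RecoveryReport(
        sensitivity=n_sel_planted / len(planted),
        n_planted=len(planted),
        n_planted_selected=n_sel_planted,
        n_selected_adjacent=n_sel_adjacent,
        n_false_positive=n_false,
        n_selected_nonplanted=n_sel_adjacent + n_false,
        n_edge_units=len(edge_rows),
    )
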