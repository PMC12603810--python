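"""End-to-end orchestration over the fixture layout.

Each step reads/writes the on-disk layout produced by the previous one so
the stages can be run (and re-run) independently: simulate -> behav ->
ersp -> cluster -> stats -> correlate.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import behavioral, brain_behavior, cluster_stats, ic_clustering, synthetic_data
from .timefreq import ERSPGrid, ERSPTensor, collapse_suppression, compute_ersp, delta_ersp

__all__ = [
    "run_simulate",
    "run_behavior",
    "run_ersp",
    "run_cluster",
    "run_stats",
    "run_correlate",
]

_CONDS = synthetic_data.CONDITIONS


def run_simulate(
    config: synthetic_data.CohortConfig, out_dir: str | Path
) -> tuple[synthetic_data.CohortTable, list]:
    """Generate a cohort plus IC epochs and write the fixture set."""
    cohort = synthetic_data.generate_cohort(config)
    ic_data = synthetic_data.simulate_cohort_ics(cohort, config)
    synthetic_data.write_fixture(cohort, ic_data, out_dir)
    return cohort, ic_data


def run_behavior(fixtures_dir: str | Path, out_dir: str | Path) -> pd.DataFrame:
    """Normalised rates, pairwise paired tests with FDR, suppression scores."""
    cohort, _ = synthetic_data.read_fixture(fixtures_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rates = behavioral.condition_rates(cohort)
    tests = behavioral.pairwise_paired_tests(rates)
    scores = behavioral.suppression_scores(rates)
    tests.to_csv(out_dir / "behavior_results.csv", index=False)
    scores.to_csv(out_dir / "suppression_scores.csv", index=False)
    return tests


def run_ersp(
    fixtures_dir: str | Path,
    out_path: str | Path,
    grid: ERSPGrid | None = None,
) -> None:
    """Compute per-IC, per-condition ERSP tensors and store them in HDF5."""
    grid = ERSPGrid.default() if grid is None else grid
    _, ic_data = synthetic_data.read_fixture(fixtures_dir)
    with h5py.File(out_path, "w") as h5:
        gg = h5.create_group("grid")
        gg.create_dataset("freqs_hz", data=grid.freqs_hz)
        gg.create_dataset("times_ms", data=grid.times_ms)
        gg.attrs["baseline_s"] = grid.baseline_s
        for ic in ic_data:
            base = h5.require_group(f"subjects/{ic.subject_id}/ics/{ic.ic_id}")
            base.create_dataset("dipole_xyz", data=ic.dipole_xyz)
            for cond, epochs in ic.epochs.items():
                tensor = compute_ersp(epochs, ic.sampling_rate, grid)
                ds = base.create_dataset(f"{cond}/ersp", data=tensor.values)
                ds.attrs["n_epochs"] = tensor.n_epochs


def _iter_ersp(h5) -> list[dict]:
    grid_grp = h5["grid"]
    grid = ERSPGrid(
        freqs_hz=grid_grp["freqs_hz"][()],
        times_s=grid_grp["times_ms"][()] / 1000.0,
        baseline_s=tuple(grid_grp.attrs["baseline_s"]),
    )
    out = []
    for sid in h5["subjects"]:
        for ic_id in h5[f"subjects/{sid}/ics"]:
            grp = h5[f"subjects/{sid}/ics/{ic_id}"]
            tensors = {
                cond: ERSPTensor(
                    values=grp[cond]["ersp"][()],
                    grid=grid,
                    n_epochs=int(grp[cond]["ersp"].attrs["n_epochs"]),
                )
                for cond in grp
                if cond != "dipole_xyz"
            }
            out.append(
                {
                    "subject_id": sid,
                    "ic_id": ic_id,
                    "dipole_xyz": grp["dipole_xyz"][()],
                    "ersp": tensors,
                }
            )
    return out


def run_cluster(
    ersp_path: str | Path,
    out_csv: str | Path,
    k: int | None = None,
    k_range=range(2, 21),
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster IC dipoles (silhouette-selected k unless given) -> clusters.csv."""
    with h5py.File(ersp_path, "r") as h5:
        ics = _iter_ersp(h5)
    xyz = np.stack([ic["dipole_xyz"] for ic in ics])
    if k is None:
        k, _ = ic_clustering.select_k_silhouette(xyz, k_range=k_range, seed=seed)
    cs = ic_clustering.cluster_dipoles(xyz, k, seed=seed)
    table = pd.DataFrame(
        {
            "subject_id": [ic["subject_id"] for ic in ics],
            "ic_id": [ic["ic_id"] for ic in ics],
            "cluster": cs.labels,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )
    table.to_csv(out_csv, index=False)
    return table


def run_stats(
    ersp_path: str | Path,
    clusters_csv: str | Path,
    fixtures_dir: str | Path,
    out_dir: str | Path,
    n_perm: int = 1000,
    seed: int = 0,
    effects=cluster_stats.EFFECTS,
    min_ics_per_group: int = 2,
) -> pd.DataFrame:
    """Cluster-mass permutation tests per spatial IC cluster and effect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort, _ = synthetic_data.read_fixture(fixtures_dir)
    group_of = dict(zip(cohort.subjects.subject_id, cohort.subjects.group))
    clusters = pd.read_csv(clusters_csv, dtype={"subject_id": str, "ic_id": str})
    with h5py.File(ersp_path, "r") as h5:
        ics = {(ic["subject_id"], ic["ic_id"]): ic for ic in _iter_ersp(h5)}
    rows = []
    rng = np.random.default_rng(seed)
    for cluster_id, members in clusters.groupby("cluster", sort=True):
        data, groups, subject_ids = [], [], []
        for _, m in members.iterrows():
            ic = ics[(m.subject_id, m.ic_id)]
            supp = collapse_suppression(ic["ersp"]["Supp_Vrb"], ic["ersp"]["Supp_Rwd"])
            data.append(np.stack([ic["ersp"]["NoSupp"].values, supp.values]))
            groups.append(group_of[m.subject_id])
            subject_ids.append(m.subject_id)
        data = np.stack(data)
        groups = np.asarray(groups)
        counts = pd.Series(groups).value_counts()
        if len(counts) < 2 or counts.min() < min_ics_per_group:
            continue  # cluster cannot support the between-group design
        for effect in effects:
            eff_seed = int(rng.integers(0, 2**31 - 1))
            try:
                null, mask = cluster_stats.wfwer_permutation_test(
                    data, groups, subject_ids, effect, n_perm=n_perm, seed=eff_seed
                )
            except ValueError:
                continue  # too few exchangeable units in this cluster

            with h5py.File(out_dir / f"stats_{cluster_id}_{effect}.h5", "w") as h5out:
                h5out.create_dataset("mask", data=mask.mask)
                h5out.create_dataset("null_max_masses", data=null.max_masses)
                h5out.attrs["threshold"] = null.threshold
                h5out.attrs["direction"] = mask.direction
            rows.append(
                {
                    "cluster": cluster_id,
                    "effect": effect,
                    "n_ics": data.shape[0],
                    "n_clusters_suprathreshold": len(mask.clusters),
                    "n_significant": int(mask.significant.sum()),
                    "mask_pixels": int(mask.mask.sum()),
                    "threshold": null.threshold,
                    "direction": mask.direction,
                }
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "stats_summary.csv", index=False)
    return summary


def run_correlate(
    ersp_path: str | Path,
    clusters_csv: str | Path,
    stats_dir: str | Path,
    scores_csv: str | Path,
    out_csv: str | Path,
    effect: str = "Interaction",
    n_boot: int = 2000,
    seed: int = 0,
    min_n: int = 5,
) -> pd.DataFrame:
    """Correlate mask-mean dERSP with behavioural suppression per cluster x group.

    Each spatial cluster is bound to its own significance mask for the given
    effect; clusters with an empty mask are skipped.
    """
    stats_dir = Path(stats_dir)
    scores = pd.read_csv(scores_csv, dtype={"subject_id": str})
    clusters = pd.read_csv(clusters_csv, dtype={"subject_id": str, "ic_id": str})
    with h5py.File(ersp_path, "r") as h5:
        ics = {(ic["subject_id"], ic["ic_id"]): ic for ic in _iter_ersp(h5)}
    group_of = dict(zip(scores.subject_id, scores.group))
    cells = []
    for cluster_id, members in clusters.groupby("cluster", sort=True):
        mask_path = stats_dir / f"stats_{cluster_id}_{effect}.h5"
        if not mask_path.exists():
            continue
        with h5py.File(mask_path, "r") as h5m:
            mask = h5m["mask"][()].astype(bool)
        if not mask.any():
            continue
        deltas, subject_ids = [], []
        for _, m in members.iterrows():
            ic = ics[(m.subject_id, m.ic_id)]
            d = delta_ersp(
                ic["ersp"]["Supp_Vrb"], ic["ersp"]["Supp_Rwd"], ic["ersp"]["NoSupp"]
            )
            deltas.append(d.values)
            subject_ids.append(m.subject_id)
        summary = brain_behavior.mask_mean_delta(deltas, subject_ids, mask)
        for sid, value in summary.items():
            cells.append(
                {
                    "cluster": cluster_id,
                    "group": group_of.get(sid),
                    "subject_id": sid,
                    "summary": value,
                }
            )
    if not cells:
        return pd.DataFrame()
    summaries = pd.DataFrame(cells)
    counts = summaries.groupby(["cluster", "group"])["subject_id"].transform("size")
    summaries = summaries[counts >= min_n]  # undersized cells cannot be tested
    if summaries.empty:
        return pd.DataFrame()
    out = brain_behavior.correlate_with_ratio(
        summaries, scores, n_boot=n_boot, seed=seed, min_n=min_n
    )
    out.to_csv(out_csv, index=False)
    return out
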