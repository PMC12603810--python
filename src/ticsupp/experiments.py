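"""Calibration and recovery studies run on the synthetic generator.

These are the package's validation experiments: each function simulates
cohorts under known ground truth, pushes them through the analysis stages,
and measures an operating characteristic (type-I error of the cluster-mass
permutation test, recovery of injected spectral effects, sampling behaviour
of the brain-behaviour correlation, behavioural test power, silhouette
k-recovery).  Problem sizes default to desk-scale settings chosen so a full
sweep runs in minutes on one CPU; every function is deterministic given its
seed.
"""

from __future__ import annotations

import numpy as np

from . import behavioral, brain_behavior, cluster_stats, ic_clustering, synthetic_data
from .timefreq import ERSPGrid, compute_ersp

__all__ = [
    "two_condition_ic_stack",
    "wfwer_null_rate",
    "effect_recovery_rate",
    "ersp_amplitude_recovery_db",
    "correlation_recovery_rate",
    "null_correlation_fdr_rate",
    "behavioral_power",
    "silhouette_k_recovery",
]

_REDUCED_GRID = dict(n_freqs=25, n_times=200)
_SFREQ = 125.0


def _reduced_grid() -> ERSPGrid:
    return ERSPGrid.regular(**_REDUCED_GRID)


def two_condition_ic_stack(
    seed: int,
    n_subjects_per_group: int = 6,
    ics_per_subject: int = 2,
    n_epochs: int = 10,
    effect_db: float = 0.0,
    band_hz: tuple[float, float] = (4.0, 8.0),
    window_s: tuple[float, float] = (-3.0, 0.0),
    grid: ERSPGrid | None = None,
):
    """Simulate a reduced two-condition cohort and compute its ERSP stack.

    Each subject contributes ``ics_per_subject`` ICs with ``n_epochs``
    pink-noise epochs per condition; ``effect_db`` injects a Suppression
    main effect (same dB in both groups) in the given band and window.
    Returns ``(data, groups, subject_ids, grid)`` where ``data`` has shape
    ``(n_ics, 2, n_freqs, n_times)`` with condition order (NoSupp, Supp).
    """
    grid = _reduced_grid() if grid is None else grid
    rng = np.random.default_rng(seed)
    effects = []
    if effect_db != 0.0:
        effects.append(
            synthetic_data.EffectSpec(
                band_hz=band_hz,
                window_s=window_s,
                amplitude_db={
                    (g, "Supp_Vrb"): effect_db for g in synthetic_data.GROUPS
                },
            )
        )
    config = synthetic_data.CohortConfig(
        n_per_group={"TDC": n_subjects_per_group, "CTD": n_subjects_per_group},
        sampling_rate=_SFREQ,
        effect_spec=effects,
        coupling_beta=0.0,
        min_events=0,
        seed=seed,
    )
    duration = 60.0 * n_epochs  # wide spacing; epoch content is what matters
    times = np.linspace(10.0, duration - 5.0, n_epochs)
    events = {
        c: synthetic_data.EventSeries(c, times, duration)
        for c in ("NoSupp", "Supp_Vrb")
    }
    data, groups, subject_ids = [], [], []
    for gi, group in enumerate(synthetic_data.GROUPS):
        for s in range(n_subjects_per_group):
            sid = f"{group}{s:02d}"
            subject = {"subject_id": sid, "group": group, "latent_ability": 0.0}
            for k in range(ics_per_subject):
                ic = synthetic_data.simulate_ic_epochs(
                    subject, events, config, rng=rng, ic_id=f"ic{k}", centroid_index=0
                )
                pair = [
                    compute_ersp(ic.epochs[c], _SFREQ, grid).values
                    for c in ("NoSupp", "Supp_Vrb")
                ]
                data.append(np.stack(pair))
                groups.append(group)
                subject_ids.append(sid)
    return np.stack(data), np.asarray(groups), np.asarray(subject_ids), grid


def wfwer_null_rate(
    n_cohorts: int = 200,
    n_perm: int = 200,
    seed: int = 0,
    effect: str = "Interaction",
    **stack_kwargs,
) -> dict:
    """Fraction of null cohorts with any wFWER-significant cluster.

    Under the global null this estimates the weak family-wise error rate of
    the cluster-mass permutation procedure; it should sit near the nominal
    0.05.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 * n_cohorts)
    hits = 0
    for i in range(n_cohorts):
        data, groups, subject_ids, _ = two_condition_ic_stack(
            int(child[2 * i] % 2**31), **stack_kwargs
        )
        _, mask = cluster_stats.wfwer_permutation_test(
            data, groups, subject_ids, effect,
            n_perm=n_perm, seed=int(child[2 * i + 1] % 2**31),
        )
        hits += bool(mask.significant.any())
    return {"rate": hits / n_cohorts, "n": n_cohorts}


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0


def effect_recovery_rate(
    n_runs: int = 50,
    effect_db: float = 3.0,
    band_hz: tuple[float, float] = (4.0, 8.0),
    window_s: tuple[float, float] = (-3.0, 0.0),
    n_perm: int = 200,
    min_jaccard: float = 0.25,
    seed: int = 0,
    **stack_kwargs,
) -> dict:
    """Recovery of an injected Suppression effect by the significance mask.

    Success means the Suppression mask overlaps the injected band x window
    region with Jaccard >= ``min_jaccard`` and has the injected sign.
    Returns the success rate over ``n_runs`` simulated cohorts and the mean
    Jaccard index.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 * n_runs)
    grid = _reduced_grid()
    target = np.zeros(grid.shape, dtype=bool)
    f_in = (grid.freqs_hz >= band_hz[0]) & (grid.freqs_hz <= band_hz[1])
    t_in = (grid.times_s >= window_s[0]) & (grid.times_s <= window_s[1])
    target[np.ix_(f_in, t_in)] = True
    successes, jaccards = 0, []
    for i in range(n_runs):
        data, groups, subject_ids, _ = two_condition_ic_stack(
            int(child[2 * i] % 2**31),
            effect_db=effect_db,
            band_hz=band_hz,
            window_s=window_s,
            grid=grid,
            **stack_kwargs,
        )
        _, mask = cluster_stats.wfwer_permutation_test(
            data, groups, subject_ids, "Suppression",
            n_perm=n_perm, seed=int(child[2 * i + 1] % 2**31),
        )
        j = _jaccard(mask.mask, target)
        jaccards.append(j)
        if j >= min_jaccard and np.sign(mask.direction) == np.sign(effect_db):
            successes += 1
    return {
        "rate": successes / n_runs,
        "mean_jaccard": float(np.mean(jaccards)),
        "n": n_runs,
    }


def ersp_amplitude_recovery_db(
    amplitude_ratio: float = 2.0,
    freq_hz: float = 10.0,
    window_s: tuple[float, float] = (-2.0, 0.0),
    n_epochs: int = 30,
    sampling_rate: float = 250.0,
    seed: int = 0,
) -> float:
    """Measured ERSP (dB) for a sinusoid whose amplitude steps by a known ratio.

    The analytic expectation is ``20*log10(amplitude_ratio)``; the measured
    value is read at the carrier frequency in the middle of the modulation
    window.  Deterministic for a fixed seed (epoch phases are drawn once).
    """
    rng = np.random.default_rng(seed)
    n = int(round(5 * sampling_rate))
    t = -5.0 + np.arange(n) / sampling_rate
    gain = np.where((t >= window_s[0]) & (t <= window_s[1]), amplitude_ratio, 1.0)
    phases = rng.uniform(0, 2 * np.pi, n_epochs)
    epochs = gain[None, :] * np.sin(
        2 * np.pi * freq_hz * t[None, :] + phases[:, None]
    )
    tensor = compute_ersp(epochs, sampling_rate, ERSPGrid.default())
    fi = np.argmin(np.abs(tensor.grid.freqs_hz - freq_hz))
    ti = np.argmin(np.abs(tensor.grid.times_s - np.mean(window_s)))
    return float(tensor.values[fi, ti])


def correlation_recovery_rate(
    n_cohorts: int = 100,
    rho: float = 0.5,
    n_subjects: int = 39,
    seed: int = 0,
) -> dict:
    """Sampling behaviour of the brain-behaviour correlation at known rho.

    For each simulated cohort the per-subject (dERSP summary, suppression
    score) pairs have population correlation ``rho``; the estimated r is
    checked against the two-sided 95% Fisher-z sampling band around rho.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_cohorts)
    z = np.arctanh(rho)
    half = 1.959963984540054 / np.sqrt(n_subjects - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    inside = 0
    rs = []
    for i in range(n_cohorts):
        pairs = synthetic_data.simulate_summary_pairs(
            n_subjects, rho, seed=int(child[i] % 2**31)
        )
        r, _ = behavioral.covariate_correlation(
            pairs.delta_summary, pairs.suppression_score
        )
        rs.append(r)
        inside += bool(lo <= r <= hi)
    return {
        "rate": inside / n_cohorts,
        "mean_r": float(np.mean(rs)),
        "band": (float(lo), float(hi)),
        "n": n_cohorts,
    }


def null_correlation_fdr_rate(
    n_cohorts: int = 100,
    n_clusters: int = 13,
    n_subjects: int = 39,
    alpha: float = 0.05,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Any-significant rate of the FDR-corrected correlation scan under the null.

    Simulates ``n_clusters`` x 2 group cells of independent (summary, score)
    pairs with zero coupling; after Benjamini-Hochberg correction across all
    cells, the probability of any rejection should stay near ``alpha``.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_cohorts * (2 * n_clusters + 1))
    hits = 0
    pos = 0
    for _ in range(n_cohorts):
        frames = []
        for cluster in range(n_clusters):
            for group in synthetic_data.GROUPS:
                pairs = synthetic_data.simulate_summary_pairs(
                    n_subjects, 0.0, seed=int(child[pos] % 2**31), group=group
                )
                pos += 1
                frames.append(
                    pd.DataFrame(
                        {
                            "cluster": cluster,
                            "group": group,
                            "subject_id": [
                                f"{group}{i}" for i in range(n_subjects)
                            ],
                            "summary": pairs.delta_summary,
                            "ratio": pairs.suppression_score,
                        }
                    )
                )
        cells = pd.concat(frames, ignore_index=True)
        out = brain_behavior.correlate_with_ratio(
            cells[["cluster", "group", "subject_id", "summary"]],
            cells[["subject_id", "ratio"]].drop_duplicates("subject_id"),
            n_boot=n_boot,
            seed=int(child[pos] % 2**31),
        )
        pos += 1
        hits += bool((out.p_fdr < alpha).any())
    return {"rate": hits / n_cohorts, "n": n_cohorts}


def behavioral_power(
    n_cohorts: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power of the NoSupp vs Supp_Rwd paired test at study-scale defaults.

    Cohorts are generated at the default group event rates, dispersions and
    sample sizes; the fraction of cohorts in which the FDR-corrected
    NoSupp vs Supp_Rwd comparison is significant is reported per group.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_cohorts)
    hits = {g: 0 for g in synthetic_data.GROUPS}
    for i in range(n_cohorts):
        config = synthetic_data.CohortConfig(seed=int(child[i] % 2**31))
        cohort = synthetic_data.generate_cohort(config)
        rates = behavioral.condition_rates(cohort)
        tests = behavioral.pairwise_paired_tests(rates)
        sel = tests[
            (tests.condition_a == "NoSupp") & (tests.condition_b == "Supp_Rwd")
        ]
        for _, row in sel.iterrows():
            if row.p_fdr < alpha:
                hits[row.group] += 1
    return {g: hits[g] / n_cohorts for g in hits} | {"n": n_cohorts}


def silhouette_k_recovery(
    n_runs: int = 20,
    k_true: int = 13,
    ics_per_cluster: int = 12,
    centroid_sd_mm: float = 4.0,
    k_range=range(2, 21),
    seed: int = 0,
) -> dict:
    """How often silhouette selection recovers the true number of dipole blobs.

    The blobs are well separated by construction: the default 4 mm scatter
    is small against the >= 35 mm spacing of the default centroids.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_runs)
    centres = np.array([xyz for _, xyz in synthetic_data.DEFAULT_CENTROIDS[:k_true]])
    hits = 0
    for i in range(n_runs):
        rng = np.random.default_rng(int(child[i] % 2**31))
        pts = np.concatenate(
            [c + rng.normal(0, centroid_sd_mm, size=(ics_per_cluster, 3)) for c in centres]
        )
        best_k, _ = ic_clustering.select_k_silhouette(
            pts, k_range=k_range, seed=int(child[i] % 2**31)
        )
        hits += best_k == k_true
    return {"rate": hits / n_runs, "n": n_runs}
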