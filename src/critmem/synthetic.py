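"""Synthetic inputs for the spike-train pipeline.

Slow-wave-sleep-like population activity is emulated as a driven branching
process with Poisson offspring: a_{t+1} ~ Poisson(σ·a_t + drive).  For
σ < 1 the process is stationary with mean drive/(1−σ); σ = 1 with positive
drive is super-critical bookkeeping-wise (the mean random-walks upward).
Optional per-event binomial subsampling emulates observing only a fraction
of the units; optional injected non-stationarities (a step change in the
drive, or up/down-state switching) exercise the rejection screen.

A full synthetic cohort mirrors the study design: conditioned (CFC) and
sham subjects, two 24 h epochs per subject, several sleep bouts per epoch,
and a behavioral freezing table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from critmem.branching import ActivitySeries, SpikeDataset, DEFAULT_BIN_WIDTH

__all__ = [
    "BranchingProcessSpec",
    "CohortSpec",
    "simulate_branching",
    "spikes_from_counts",
    "make_cohort",
]


@dataclass
class BranchingProcessSpec:
    """Parameters of one driven-branching-process realization.

    ``nonstationarity`` is None, ``("drift", factor)`` — the drive jumps to
    factor × drive at the series midpoint — or
    ``("updown", period, low, high)`` — the drive alternates between low
    and high every ``period`` bins.
    """

    sigma: float
    drive_rate: float
    n_bins: int
    subsample_prob: float = 1.0
    nonstationarity: tuple | None = None
    bin_width: float = DEFAULT_BIN_WIDTH
    a0: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 < self.subsample_prob <= 1:
            raise ValueError("subsample_prob must be in (0, 1]")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def _drive_series(spec: BranchingProcessSpec) -> np.ndarray:
    drive = np.full(spec.n_bins, spec.drive_rate, dtype=float)
    ns = spec.nonstationarity
    if ns is None:
        return drive
    kind = ns[0]
    if kind == "drift":
        factor = float(ns[1])
        drive[spec.n_bins // 2 :] *= factor
    elif kind == "updown":
        period, low, high = int(ns[1]), float(ns[2]), float(ns[3])
        phase = (np.arange(spec.n_bins) // period) % 2
        drive = np.where(phase == 0, high, low)
    else:
        raise ValueError(f"unknown nonstationarity kind {kind!r}")
    return drive


def simulate_branching(
    spec: BranchingProcessSpec,
    rng: np.random.Generator | None = None,
) -> ActivitySeries:
    """Generate a_{t+1} ~ Poisson(σ·a_t + drive_t), optionally binomially
    subsampled per event.  Fully determined by spec.seed (or the passed
    generator)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    drive = _drive_series(spec)
    if spec.a0 is not None:
        a = int(spec.a0)
    elif spec.sigma < 1:
        a = int(rng.poisson(drive[0] / (1.0 - spec.sigma)))
    else:
        a = int(rng.poisson(drive[0])) if drive[0] > 0 else 1

    full = np.empty(spec.n_bins, dtype=np.int64)
    for t in range(spec.n_bins):
        a = int(rng.poisson(spec.sigma * a + drive[t]))
        full[t] = a
    if spec.subsample_prob < 1.0:
        observed = rng.binomial(full, spec.subsample_prob)
    else:
        observed = full
    return ActivitySeries(counts=observed, bin_width=spec.bin_width)


def spikes_from_counts(
    series: ActivitySeries,
    n_units: int,
    rng: np.random.Generator | int | None = None,
    *,
    t_start: float = 0.0,
) -> list[np.ndarray]:
    """Scatter each bin's count as uniformly timed spikes within the bin and
    assign them to units multinomially (uniform across units).

    Re-binning the result with the same bin width returns the original
    counts exactly.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    counts = series.counts
    total = int(counts.sum())
    bin_idx = np.repeat(np.arange(counts.size), counts)
    offsets = rng.random(total)
    # strictly inside the half-open bin: nextafter guards the upper edge
    offsets = np.minimum(offsets, np.nextafter(1.0, 0.0))
    times = t_start + (bin_idx + offsets) * series.bin_width
    unit_of = rng.integers(n_units, size=total)
    return [np.sort(times[unit_of == u]) for u in range(n_units)]


@dataclass
class CohortSpec:
    """Design of a synthetic conditioning study.

    Defaults mirror the study design: 5 conditioned (CFC) and 3 sham
    subjects, each with a baseline and a post-conditioning epoch of several
    SWS bouts (durations log-uniform between 2 and 10 minutes).  Baseline
    dynamics sit near criticality (σ ≈ 0.99); conditioning shifts CFC
    subjects to sub-critical (−0.05) and sham subjects barely (−0.01).
    The drive is chosen per epoch to hold the mean observed rate fixed, so
    the σ shift — not a rate change — is the signal.
    """

    n_cfc: int = 5
    n_sham: int = 3
    bouts_per_epoch: int = 6
    sigma_baseline: dict = field(
        default_factory=lambda: {"CFC": 0.99, "Sham": 0.99}
    )
    sigma_post: dict = field(
        default_factory=lambda: {"CFC": 0.94, "Sham": 0.98}
    )
    mean_rate_per_bin: float = 4.0  # pooled, after subsampling
    subsample_prob: float = 0.25
    n_units: int = 30
    bout_minutes: tuple[float, float] = (2.0, 10.0)
    bin_width: float = DEFAULT_BIN_WIDTH
    # freezing %: (baseline mean, baseline sd, test mean, test sd)
    freezing: dict = field(
        default_factory=lambda: {
            "CFC": (8.0, 3.0, 45.0, 10.0),
            "Sham": (8.0, 3.0, 12.0, 5.0),
        }
    )

    def __post_init__(self):
        if self.n_cfc < 1 or self.n_sham < 1:
            raise ValueError("need at least one subject per group")
        if self.bouts_per_epoch < 1:
            raise ValueError("bouts_per_epoch must be >= 1")


def _subject_dataset(
    spec: CohortSpec, subject_id: str, condition: str, rng: np.random.Generator
) -> tuple[SpikeDataset, dict]:
    lo, hi = (m * 60.0 for m in spec.bout_minutes)
    units: list[list[np.ndarray]] = [[] for _ in range(spec.n_units)]
    bout_rows = []
    t_cursor = 0.0
    for epoch, sigma_map in (
        ("baseline", spec.sigma_baseline),
        ("post_cond", spec.sigma_post),
    ):
        sigma = sigma_map[condition]
        # underlying rate so that the observed (subsampled) rate is fixed
        rate_full = spec.mean_rate_per_bin / spec.subsample_prob
        drive = rate_full * (1.0 - sigma)
        for _ in range(spec.bouts_per_epoch):
            dur = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            n_bins = int(dur / spec.bin_width)
            bp = BranchingProcessSpec(
                sigma=sigma,
                drive_rate=drive,
                n_bins=n_bins,
                subsample_prob=spec.subsample_prob,
                bin_width=spec.bin_width,
            )
            series = simulate_branching(bp, rng)
            spikes = spikes_from_counts(series, spec.n_units, rng, t_start=t_cursor)
            for u in range(spec.n_units):
                units[u].append(spikes[u])
            bout_rows.append(
                {
                    "start": t_cursor,
                    "end": t_cursor + n_bins * spec.bin_width,
                    "epoch": epoch,
                    "state": "SWS",
                }
            )
            t_cursor += dur + 60.0  # inter-bout gap

    dataset = SpikeDataset(
        units=[np.concatenate(u) if u else np.empty(0) for u in units],
        bouts=pd.DataFrame(bout_rows),
        subject_id=subject_id,
        condition=condition,
    )
    fb_m, fb_s, ft_m, ft_s = spec.freezing[condition]
    behavior = {
        "subject": subject_id,
        "condition": condition,
        "freeze_baseline_pct": float(np.clip(rng.normal(fb_m, fb_s), 0, 100)),
        "freeze_test_pct": float(np.clip(rng.normal(ft_m, ft_s), 0, 100)),
    }
    return dataset, behavior


def make_cohort(
    spec: CohortSpec,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[SpikeDataset], pd.DataFrame]:
    """Generate the full synthetic study; optionally write it to disk in the
    pipeline's file formats (per-subject spike and bout files, a subject
    manifest, and a behavior table).

    Identical specs and seeds produce identical datasets (and byte-identical
    files).
    """
    ss = np.random.SeedSequence(seed)
    subjects = [("CFC", i) for i in range(spec.n_cfc)] + [
        ("Sham", i) for i in range(spec.n_sham)
    ]
    datasets, behavior_rows = [], []
    for (cond, i), child in zip(subjects, ss.spawn(len(subjects))):
        sid = f"{cond.lower()}{i + 1:02d}"
        ds, beh = _subject_dataset(spec, sid, cond, np.random.default_rng(child))
        datasets.append(ds)
        behavior_rows.append(beh)
    behavior = pd.DataFrame(behavior_rows)

    if out_dir is not None:
        from critmem import io as cio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest_rows = []
        for ds in datasets:
            spike_file = out / f"{ds.subject_id}_spikes.tsv"
            bout_file = out / f"{ds.subject_id}_bouts.tsv"
            cio.write_spikes(ds, spike_file)
            cio.write_bouts(ds.bouts, bout_file)
            manifest_rows.append(
                {
                    "subject": ds.subject_id,
                    "condition": ds.condition,
                    "spike_file": spike_file.name,
                    "bout_file": bout_file.name,
                }
            )
        pd.DataFrame(manifest_rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
        meta = {"seed": seed, "spec": {k: str(v) for k, v in vars(spec).items()}}
        (out / "cohort_meta.json").write_text(json.dumps(meta, indent=2))

    return datasets, behavior
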