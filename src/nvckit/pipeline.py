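"""End-to-end orchestration: simulate -> extract -> normalize -> onset -> TF -> vasomotion.

A run is fully reproducible from its configuration plus seed; every stage
materializes its artifacts (CSV/JSON) under the output directory and logs
one structured line.  ``reproduce_state_contrast`` builds the synthetic twin
of the awake-vs-anesthetized transfer-function comparison: a slow-kernel
"anesthetized-like" ensemble and a fast-kernel "awake-like" ensemble are
simulated, a TF is fitted to each ensemble mean, and both TFs are
cross-applied to every awake-like network, yielding paired prediction
correlations and rising slopes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .onset import SigmoidOnsetModel
from .synthdata import GroundTruth, make_trial_set, write_trial_set
from .tf import FitConfig, TransferFunctionModel, compare_states
from .trials import average_trials, percent_change, zscore_trial
from .vaso import vasomotion_profile

logger = logging.getLogger("nvckit.pipeline")

__all__ = ["RunConfig", "NetworkReport", "run", "reproduce_state_contrast"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (YAML-serializable)."""

    seed: int = 0
    outdir: str = "nvc_run"
    n_arbors: int = 2
    n_trials: int = 4
    # stimulus protocol: 5 Hz / 5 s anesthetized-like, 90 Hz / 3 s awake-like
    stim_rate_hz: float = 5.0
    stim_duration_s: float = 5.0
    stim_onset_s: float = 10.0
    trace_rate_hz: float = 10.0
    duration_s: float = 35.0
    baseline_s: float = 9.5
    baseline_diameter_um: float = 10.0
    onset_levels: tuple[float, ...] = (10.0, 25.0, 50.0)
    tf_runs_round1: int = 20
    tf_runs_round2: int = 20
    tf_n_iter: int = 80
    vaso_band: tuple[float, float] = (0.02, 1.0)
    vaso_cutoff_hz: float = 0.2
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_arbors < 1:
            raise ValueError("config must request at least one arbor and one trial")
        if self.baseline_s > self.stim_onset_s:
            raise ValueError("baseline cannot extend past stimulus onset")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("onset_levels", "vaso_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["onset_levels"] = list(self.onset_levels)
        d["vaso_band"] = list(self.vaso_band)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def ground_truth(self, arbor: int) -> GroundTruth:
        kw = dict(self.truth)
        if "tf_params" in kw:
            kw["tf_params"] = tuple(kw["tf_params"])
        kw["seed"] = self.seed * 1009 + arbor
        return GroundTruth(**kw)

    def fit_config(self) -> FitConfig:
        return FitConfig(
            runs_round1=self.tf_runs_round1,
            runs_round2=self.tf_runs_round2,
            n_iter=self.tf_n_iter,
        )


@dataclass
class NetworkReport:
    """All per-arbor results plus provenance."""

    onsets: pd.DataFrame
    tf_fits: pd.DataFrame
    vasomotion: pd.DataFrame
    config_hash: str
    seed: int
    version: str

    def to_json(self, path) -> None:
        payload = {
            "provenance": {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
            },
            "onsets": self.onsets.to_dict(orient="records"),
            "tf_fits": self.tf_fits.to_dict(orient="records"),
            "vasomotion": self.vasomotion.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _stage(name: str, **kv) -> None:
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in kv.items()))


def run(config: RunConfig) -> NetworkReport:
    """Execute all stages on simulated data and write artifacts.

    Stage order: simulate trials -> write CSVs -> z-score + average ->
    sigmoid onset fits -> TF fit on mean traces -> vasomotion profiles ->
    report JSON.  A stage failure aborts with the stage named; artifacts
    written so far are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    _stage("config", hash=chash, seed=config.seed)
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)

    onset_rows, tf_rows, vaso_rows = [], [], []
    base_win = (config.stim_onset_s - config.baseline_s, config.stim_onset_s)
    for arbor in range(config.n_arbors):
        truth = config.ground_truth(arbor)
        common = dict(
            truth=truth,
            stim_onset=config.stim_onset_s,
            stim_duration=config.stim_duration_s,
            rate=config.trace_rate_hz,
            duration=config.duration_s,
        )
        try:
            ca_set = make_trial_set(config.n_trials, "calcium", **common)
            dia_set = make_trial_set(
                config.n_trials, "diameter",
                baseline_offset=config.baseline_diameter_um, **common,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed for arbor {arbor}: {exc}")
        write_trial_set(ca_set, outdir / f"arbor{arbor}_calcium.csv")
        write_trial_set(dia_set, outdir / f"arbor{arbor}_diameter.csv")
        _stage("simulate", arbor=arbor, n_trials=config.n_trials)

        # normalize + average
        def _restrict(trace):
            return replace_baseline(trace, base_win)

        ca_z = [zscore_trial(_restrict(t)) for t in ca_set.trials]
        dia_z = [zscore_trial(_restrict(t)) for t in dia_set.trials]
        ca_mean = average_trials(ca_z)
        dia_mean = average_trials(dia_z)
        _stage("normalize", arbor=arbor)

        # onset on the rising limb (baseline start through the response peak)
        peak_t = float(dia_mean.time[int(np.argmax(dia_mean.z))])
        sig = SigmoidOnsetModel(
            dia_mean.time, dia_mean.z,
            fit_window=(base_win[0], peak_t + 1e-9),
            stim_onset=config.stim_onset_s,
        ).fit()
        res = sig.onset_times(levels=config.onset_levels)
        onset_rows.append(
            {
                "arbor_id": f"arbor{arbor}",
                "modality": "diameter",
                "A": sig.A, "B": sig.B, "C": sig.C, "D": sig.D, "rss": sig.rss,
                "t10_s": res.t10, "t25_s": res.t25, "t50_s": res.t50,
                "peak_z": res.peak, "flags": ",".join(res.flags),
            }
        )
        _stage("onset", arbor=arbor, t25=res.t25)

        # transfer function between mean traces
        model = TransferFunctionModel(
            (ca_mean.time, ca_mean.z), (dia_mean.time, dia_mean.z),
            config=config.fit_config(),
        )
        fit = model.fit(seed=config.seed * 997 + arbor)
        tf_rows.append(
            {
                "arbor_id": f"arbor{arbor}",
                **fit.tf.to_dict(),
                "rss": fit.rss, "r2": fit.r2, "pearson_r": fit.pearson_r,
                "seed": fit.seed,
            }
        )
        fit.to_json(outdir / f"arbor{arbor}_tf.json")
        _stage("tf", arbor=arbor, r2=round(fit.r2, 4))

        # vasomotion on percent-change diameter trials
        for i, trial in enumerate(dia_set.trials):
            prof = vasomotion_profile(
                percent_change(_restrict(trial)),
                band=config.vaso_band, cutoff=config.vaso_cutoff_hz,
            )
            vaso_rows.append(
                {
                    "arbor_id": f"arbor{arbor}", "trial_id": i,
                    "bandpower": prof.bandpower_02_1, "phase": prof.phase,
                    "flags": ",".join(prof.flags),
                }
            )
        _stage("vaso", arbor=arbor, n=len(dia_set.trials))

    onsets = pd.DataFrame(onset_rows)
    tf_fits = pd.DataFrame(tf_rows)
    vaso = pd.DataFrame(vaso_rows)
    onsets.to_csv(outdir / "onsets.csv", index=False)
    tf_fits.to_csv(outdir / "tf_fits.csv", index=False)
    vaso.to_csv(outdir / "vasomotion.csv", index=False)
    report = NetworkReport(
        onsets=onsets, tf_fits=tf_fits, vasomotion=vaso,
        config_hash=chash, seed=config.seed, version=__version__,
    )
    report.to_json(outdir / "report.json")
    _stage("report", path=str(outdir / "report.json"))
    return report


def replace_baseline(trace, baseline_window):
    """Trace copy with the analysis baseline window installed."""
    from dataclasses import replace as _replace

    return _replace(trace, baseline_window=tuple(baseline_window))


# ---------------------------------------------------------------------------
# awake-vs-anesthetized synthetic contrast

AN_TRUTH = GroundTruth(tf_params=(2.0, 0.8, 0.6, 8.0), noise_sd=0.3,
                       vasomotion_amplitude=2.0, seed=0)
AW_TRUTH = GroundTruth(tf_params=(1.6, 2.5, 0.15, 6.0), noise_sd=0.3,
                       vasomotion_amplitude=2.0, seed=0)


def _ensemble_mean(truth: GroundTruth, n_trials: int, stim_duration: float,
                   rate: float = 10.0, stim_onset: float = 10.0,
                   duration: float = 30.0):
    ca_set = make_trial_set(n_trials, "calcium", truth, stim_onset=stim_onset,
                            stim_duration=stim_duration, rate=rate,
                            duration=duration)
    va_set = make_trial_set(n_trials, "diameter", truth, stim_onset=stim_onset,
                            stim_duration=stim_duration, rate=rate,
                            duration=duration)
    t = ca_set.trials[0].time
    ca = np.mean([tr.value for tr in ca_set.trials], axis=0)
    va = np.mean([tr.value for tr in va_set.trials], axis=0)
    return t, ca, va


def reproduce_state_contrast(
    seed: int,
    n_networks: int = 20,
    trials_per_network: int = 6,
    fit_config: FitConfig | None = None,
) -> pd.DataFrame:
    """Synthetic twin of the cross-brain-state TF comparison.

    Simulates an anesthetized-like ensemble (slow kernel, 5 s stimulus) and
    an awake-like ensemble (fast kernel, 3 s stimulus); fits TF_AN and TF_AW
    on the respective ensemble means; cross-applies both to each simulated
    awake-like network.  Returns one row per network with the Pearson r and
    rising slope (sigmoid D) of each TF's prediction
    (columns r_aw, r_an, slope_aw, slope_an).
    """
    fit_config = fit_config or FitConfig.small()
    an_truth = replace(AN_TRUTH, seed=seed * 7919 + 1)
    aw_truth = replace(AW_TRUTH, seed=seed * 7919 + 2)

    t, ca_an, va_an = _ensemble_mean(an_truth, 12, stim_duration=5.0)
    _, ca_aw, va_aw = _ensemble_mean(aw_truth, 12, stim_duration=3.0)
    tf_an = TransferFunctionModel((t, ca_an), (t, va_an), config=fit_config).fit(
        seed=seed * 2 + 1
    ).tf
    tf_aw = TransferFunctionModel((t, ca_aw), (t, va_aw), config=fit_config).fit(
        seed=seed * 2 + 2
    ).tf
    _stage("state_fit", tf_an_mode=round(tf_an.mode, 3), tf_aw_mode=round(tf_aw.mode, 3))

    ca_set, obs_set = [], []
    for i in range(n_networks):
        truth_i = replace(AW_TRUTH, seed=seed * 7919 + 100 + i)
        t_i, ca_i, va_i = _ensemble_mean(truth_i, trials_per_network,
                                         stim_duration=3.0)
        ca_set.append((t_i, ca_i))
        obs_set.append((t_i, va_i))
    out = compare_states(tf_aw, tf_an, ca_set, obs_set)
    out = out.rename(
        columns={"r_a": "r_aw", "r_b": "r_an",
                 "slope_a": "slope_aw", "slope_b": "slope_an"}
    )
    _stage("state_contrast", n=n_networks,
           aw_wins=int((out.r_aw > out.r_an).sum()))
    return out
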