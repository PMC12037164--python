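"""End-to-end orchestration of the silent-speech tracking analysis.

The pipeline runs the three analysis steps on every subject and condition:

1. coherence between the stimuli (speech envelope, lip trace) and the
   ocular channel;
2. coherence between the stimuli and each neural channel;
3. partial coherence between the stimuli and each neural channel with the
   ocular channel partialized out;

followed by forward-minus-backward cluster permutation t-tests per step,
the mixed 2x3 ANOVA on band-averaged contrasts with post hoc tests, ROI
peak selection, and the blink-rate / envelope-at-blink supplementary
analysis.  One master seed spawns independent substreams for the cohort
and for the permutations, so changing the permutation count does not
change the synthetic data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .clusterstats import (AnovaResult, ClusterResult, cluster_perm_ttest,
                           cluster_perm_mixed_anova, grid_product_adjacency,
                           point_anova)
from .connectivity import (ContrastSpectrum, band_average, coherence,
                           partial_coherence, roi_peak_select)
from .ocular_events import (blink_condition_ttest, detect_blinks,
                            envelope_at_blinks)
from .prep import preprocess_subject
from .spectral import accumulate_csd, default_freq_grid, mtm_spectra
from .synthgen import CONDITIONS, CohortSpec, SubjectData, make_cohort

__all__ = ["RunConfig", "run_pipeline", "write_report", "subject_coherence"]


@dataclass
class RunConfig:
    """Fully serializable run configuration.

    A run re-executed from its logged config and seed is bit-identical.
    """

    cohort: dict = field(default_factory=dict)
    hp: float = 0.1
    lp: float = 12.0
    epoch_length: float = 6.0
    half_bandwidth: float = 0.5
    f_max: float = 5.0
    cluster_alpha: float = 0.01
    alpha: float = 0.05
    n_perm: int = 1000
    low_band: tuple = (0.0, 1.0)     # band average "below 1 Hz"
    roi: list | None = None          # neural channel subset for peak pick
    run_anova: bool = True
    run_blinks: bool = True
    seed: int = 0

    def cohort_spec(self, seed: int) -> CohortSpec:
        kw = dict(self.cohort)
        kw["seed"] = seed
        return CohortSpec(**kw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["low_band"] = list(self.low_band)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "low_band" in d:
            d["low_band"] = tuple(d["low_band"])
        return cls(**d)


def _spawn_seeds(seed: int, n: int = 2) -> list[int]:
    """Named substreams below 2**31 derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2 ** 31) for s in state]


def subject_coherence(sub: SubjectData, config: RunConfig) -> dict:
    """Run the three coherence steps for one subject.

    Returns per condition: the coherence spectra of the ocular channel and
    of each neural channel with both stimuli, the ocular-partialized
    neural coherence, and the frequency grid / estimate count.
    """
    out = {"subject_id": sub.subject_id, "group": sub.group}
    freqs = default_freq_grid(config.epoch_length, config.f_max)
    for condition in CONDITIONS:
        rec = sub.recordings[condition]
        stim = sub.stimuli[condition]
        epochs = preprocess_subject(rec, stim, hp=config.hp, lp=config.lp,
                                    epoch_length=config.epoch_length)
        spectra = mtm_spectra(epochs, freqs,
                              half_bandwidth=config.half_bandwidth)
        csd = accumulate_csd(spectra)
        neural = [n for n, r in zip(epochs.channel_names,
                                    epochs.channel_roles) if r == "neural"]
        step1 = {s: coherence(csd, "ocular", s) for s in ("envelope", "lip")}
        step2 = {s: {ch: coherence(csd, ch, s) for ch in neural}
                 for s in ("envelope", "lip")}
        step3 = {s: {ch: partial_coherence(csd, ch, s, "ocular")
                     for ch in neural} for s in ("envelope", "lip")}
        out[condition] = {"ocular": step1, "neural": step2,
                          "neural_partial": step3, "n_est": csd.n_est}
    out["freqs"] = freqs
    out["neural_channels"] = neural
    return out


def _contrast_array(per_subject: list, extract) -> np.ndarray:
    """Stack forward-minus-backward contrast values across subjects."""
    rows = []
    for sub in per_subject:
        cf = extract(sub["forward"])
        cb = extract(sub["backward"])
        rows.append(cf.values - cb.values)
    return np.asarray(rows)


def run_pipeline(config: RunConfig,
                 cohort: list[SubjectData] | None = None) -> dict:
    """Execute the full analysis and return the results bundle.

    ``cohort`` may be supplied (e.g. loaded from files); otherwise it is
    generated from ``config.cohort`` with a seed substream of
    ``config.seed``.
    """
    cohort_seed, perm_seed = _spawn_seeds(config.seed)
    if cohort is None:
        cohort = make_cohort(config.cohort_spec(cohort_seed))
    if not cohort:
        raise ValueError("empty cohort")

    per_subject = [subject_coherence(s, config) for s in cohort]
    freqs = per_subject[0]["freqs"]
    neural = per_subject[0]["neural_channels"]
    n_freq = freqs.size
    groups = np.array([s["group"] for s in per_subject])

    bundle = {
        "config": config,
        "freqs": freqs,
        "groups": groups,
        "subjects": [s["subject_id"] for s in per_subject],
        "neural_channels": neural,
        "per_subject": per_subject,
        "params": {
            "hp": config.hp, "lp": config.lp,
            "epoch_length": config.epoch_length,
            "half_bandwidth": config.half_bandwidth,
            "freq_grid": [float(f) for f in freqs],
            "cluster_alpha": config.cluster_alpha,
            "n_perm": config.n_perm, "seed": config.seed,
            "cohort_seed": cohort_seed, "perm_seed": perm_seed,
            "version": __version__,
        },
    }

    # -- step 1: ocular-stimulus cluster t-tests (frequency chain) --------
    clusters = {}
    contrasts_oc = {}
    for stimn in ("envelope", "lip"):
        arr = _contrast_array(per_subject, lambda c, s=stimn: c["ocular"][s])
        contrasts_oc[stimn] = arr
        clusters[f"ocular_{stimn}"] = cluster_perm_ttest(
            arr, adjacency=None, cluster_alpha=config.cluster_alpha,
            n_perm=config.n_perm, seed=perm_seed)

    # -- steps 2-3: neural raw and partial (frequency x channel grid) -----
    adj = grid_product_adjacency(n_freq, n_space=len(neural))
    neural_arrays = {}
    for key, field_name in (("neural", "neural"),
                            ("neural_partial", "neural_partial")):
        for stimn in ("envelope", "lip"):
            rows = []
            for sub in per_subject:
                diff = np.concatenate([
                    sub["forward"][field_name][stimn][ch].values
                    - sub["backward"][field_name][stimn][ch].values
                    for ch in neural])
                rows.append(diff)
            arr = np.asarray(rows)
            neural_arrays[(key, stimn)] = arr
            clusters[f"{key}_{stimn}"] = cluster_perm_ttest(
                arr, adjacency=adj, cluster_alpha=config.cluster_alpha,
                n_perm=config.n_perm, seed=perm_seed)
    bundle["clusters"] = clusters
    bundle["ocular_contrasts"] = contrasts_oc
    bundle["neural_contrasts"] = neural_arrays

    # -- ROI peak selection on the envelope contrast ----------------------
    roi = config.roi if config.roi else neural
    mean_contrast = {
        ch: ContrastSpectrum(
            values=np.mean([sub["forward"]["neural"]["envelope"][ch].values
                            - sub["backward"]["neural"]["envelope"][ch].values
                            for sub in per_subject], axis=0),
            freqs=freqs, pair=(ch, "envelope"))
        for ch in roi}
    peak = roi_peak_select(mean_contrast, roi, config.low_band)
    roi_raw = np.array([
        [band_average(sub[c]["neural"]["envelope"][peak], config.low_band)
         for c in CONDITIONS] for sub in per_subject])
    roi_partial = np.array([
        [band_average(sub[c]["neural_partial"]["envelope"][peak],
                      config.low_band)
         for c in CONDITIONS] for sub in per_subject])
    from scipy import stats as _st
    cond_t = _st.ttest_rel(roi_raw[:, 0], roi_raw[:, 1])
    rawpart_t = _st.ttest_rel(roi_raw[:, 0] - roi_raw[:, 1],
                              roi_partial[:, 0] - roi_partial[:, 1])
    bundle["roi"] = {
        "channel": peak, "band": config.low_band,
        "raw": roi_raw, "partial": roi_partial,
        "condition_ttest": {"t": float(cond_t.statistic),
                            "df": float(cond_t.df),
                            "p": float(cond_t.pvalue)},
        "raw_vs_partial_ttest": {"t": float(rawpart_t.statistic),
                                 "df": float(rawpart_t.df),
                                 "p": float(rawpart_t.pvalue)},
    }

    # -- mixed 2x3 ANOVA on ocular contrasts ------------------------------
    n_groups_ok = sum(np.sum(groups == g) >= 2 for g in set(groups))
    if config.run_anova and n_groups_ok >= 2:
        spectra = np.stack([contrasts_oc["envelope"],
                            contrasts_oc["lip"]], axis=1)
        bundle["anova_cluster"] = cluster_perm_mixed_anova(
            spectra, groups, adjacency=None,
            cluster_alpha=config.cluster_alpha, n_perm=config.n_perm,
            seed=perm_seed)
        low = np.array([(band_average_from(arr, freqs, config.low_band))
                        for arr in (contrasts_oc["envelope"],
                                    contrasts_oc["lip"])])
        bundle["anova_point"] = point_anova(low.T, groups)
    elif config.run_anova:
        bundle["anova_cluster"] = None
        bundle["anova_point"] = None

    # -- blink supplementary analysis -------------------------------------
    if config.run_blinks:
        rates = {c: [] for c in CONDITIONS}
        env_z = {c: [] for c in CONDITIONS}
        for sub in cohort:
            for c in CONDITIONS:
                rec = sub.recordings[c]
                ev = detect_blinks(rec.data[rec.ocular_index], rec.rate,
                                   condition=c)
                rates[c].append(ev.rate_hz)
                env_z[c].append(
                    envelope_at_blinks(ev, sub.stimuli[c]["envelope"]))
        bundle["blinks"] = {
            "rates": rates,
            "envelope_z": env_z,
            "rate_ttest": blink_condition_ttest(rates["forward"],
                                                rates["backward"]),
            "envelope_z_ttest": blink_condition_ttest(env_z["forward"],
                                                      env_z["backward"]),
        }
    return bundle


def band_average_from(arr: np.ndarray, freqs: np.ndarray,
                      band: tuple) -> np.ndarray:
    """Row-wise unweighted mean of contrast values over grid frequencies
    with f_lo <= f < f_hi."""
    lo, hi = band
    mask = (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)
    if not mask.any():
        raise ValueError(f"band {band} does not intersect the grid")
    return np.asarray(arr)[..., mask].mean(axis=-1)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _cluster_json(result: ClusterResult, freqs: np.ndarray,
                  n_freq: int) -> list:
    out = []
    for c in result.clusters:
        out.append({
            "freqs_hz": [float(freqs[m % n_freq]) for m in c.members],
            "channels": sorted({int(m // n_freq) for m in c.members}),
            "mass": c.mass, "p": c.p, "sign": c.sign,
        })
    return out


def _anova_json(res: AnovaResult | None) -> dict | None:
    if res is None:
        return None
    out = {}
    for name, eff in res.effects.items():
        entry = {"dfn": eff["dfn"], "dfd": eff["dfd"]}
        if "p" in eff:
            entry["F"] = eff["F"]
            entry["p"] = eff["p"]
        else:
            entry["clusters"] = [
                {"mass": c.mass, "p": c.p, "members": c.members.tolist()}
                for c in eff["result"].clusters]
        out[name] = entry
    return out


def write_report(bundle: dict, outdir: str | Path) -> Path:
    """Write the results bundle: tidy tables, JSON statistics, a JSON
    index and a human-readable summary.  Returns the summary path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing = [k for k in ("config", "freqs", "clusters") if k not in bundle]
    if missing:
        raise ValueError(f"incomplete bundle, missing: {missing}")
    config: RunConfig = bundle["config"]
    freqs = bundle["freqs"]
    n_freq = freqs.size
    index = {"version": __version__, "files": []}

    config.to_yaml(outdir / "config.yaml")
    (outdir / "params.json").write_text(
        json.dumps(bundle["params"], indent=1))
    index["files"] += ["config.yaml", "params.json"]

    # tidy contrast table
    rows = []
    for stimn, arr in bundle["ocular_contrasts"].items():
        for i, sid in enumerate(bundle["subjects"]):
            for j, f in enumerate(freqs):
                rows.append({"subject": sid,
                             "group": bundle["groups"][i],
                             "pair": f"ocular-{stimn}",
                             "frequency_hz": float(f),
                             "contrast": float(arr[i, j])})
    pd.DataFrame(rows).to_csv(outdir / "ocular_contrasts.tsv", sep="\t",
                              index=False)
    index["files"].append("ocular_contrasts.tsv")

    cluster_json = {}
    for name, res in bundle["clusters"].items():
        cluster_json[name] = {
            "threshold": res.threshold,
            "cluster_alpha": res.cluster_alpha,
            "n_perm": res.n_perm,
            "clusters": _cluster_json(res, freqs, n_freq),
        }
    (outdir / "clusters.json").write_text(json.dumps(cluster_json, indent=1))
    index["files"].append("clusters.json")

    anova = {"cluster": _anova_json(bundle.get("anova_cluster")),
             "point": _anova_json(bundle.get("anova_point"))}
    (outdir / "anova.json").write_text(json.dumps(anova, indent=1))
    index["files"].append("anova.json")
    for key in ("anova_cluster", "anova_point"):
        res = bundle.get(key)
        if res is not None and res.posthoc is not None:
            res.posthoc.to_csv(outdir / f"{key}_posthoc.tsv", sep="\t",
                               index=False)
            index["files"].append(f"{key}_posthoc.tsv")

    if "roi" in bundle:
        roi = bundle["roi"]
        (outdir / "roi.json").write_text(json.dumps(
            {"channel": roi["channel"], "band": list(roi["band"]),
             "condition_ttest": roi["condition_ttest"],
             "raw_vs_partial_ttest": roi["raw_vs_partial_ttest"]}, indent=1))
        index["files"].append("roi.json")
    if "blinks" in bundle:
        (outdir / "blinks.json").write_text(json.dumps(
            {"rate_ttest": bundle["blinks"]["rate_ttest"],
             "envelope_z_ttest": bundle["blinks"]["envelope_z_ttest"]},
            indent=1))
        index["files"].append("blinks.json")

    # human-readable summary
    lines = ["# Silent-speech tracking run summary", ""]
    alpha = config.alpha
    any_test = False
    for name, res in bundle["clusters"].items():
        any_test = True
        sig = res.significant(alpha)
        if sig:
            for c in sig:
                fs = sorted(freqs[m % n_freq] for m in c.members)
                lines.append(
                    f"- {name}: significant {'positive' if c.sign > 0 else 'negative'}"
                    f" cluster {fs[0]:.2f}-{fs[-1]:.2f} Hz"
                    f" (mass {c.mass:.1f}, p = {c.p:.4f})")
        else:
            lines.append(f"- {name}: no significant cluster at alpha={alpha}")
    for key in ("anova_point",):
        res = bundle.get(key)
        if res is not None:
            any_test = True
            for eff, e in res.effects.items():
                lines.append(
                    f"- ANOVA {eff}: F({e['dfn']},{e['dfd']}) = "
                    f"{e['F']:.2f}, p = {e['p']:.4f}")
    if "roi" in bundle:
        r = bundle["roi"]
        lines.append(
            f"- ROI peak channel {r['channel']}: forward vs backward "
            f"t({r['condition_ttest']['df']:.0f}) = "
            f"{r['condition_ttest']['t']:.2f}, "
            f"p = {r['condition_ttest']['p']:.4f}; raw-vs-partial contrast "
            f"p = {r['raw_vs_partial_ttest']['p']:.4f}")
    if "blinks" in bundle:
        bt = bundle["blinks"]
        lines.append(
            f"- blink rate: forward {bt['rate_ttest']['mean_forward']:.3f} Hz"
            f" vs backward {bt['rate_ttest']['mean_backward']:.3f} Hz, "
            f"p = {bt['rate_ttest']['p']:.3f}")
        lines.append(
            f"- envelope z at blinks: forward "
            f"{bt['envelope_z_ttest']['mean_forward']:.3f} vs backward "
            f"{bt['envelope_z_ttest']['mean_backward']:.3f}, "
            f"p = {bt['envelope_z_ttest']['p']:.3f}")
    if not any_test:
        lines.append("no tests run")
    summary = outdir / "summary.md"
    summary.write_text("\n".join(lines) + "\n")
    index["files"].append("summary.md")
    (outdir / "index.json").write_text(json.dumps(index, indent=1))
    return summary
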