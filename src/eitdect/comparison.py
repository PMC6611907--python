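"""Method-comparison statistics and the full synthetic study replication.

Statistics: Pearson correlation, Bland-Altman agreement (bias and 95% limits
bias +- 1.96 sd of the paired differences), the quadrant "goodness score"
(mean absolute difference of two four-quadrant percentage vectors, lower is
better), a paired t-test for left-vs-right shares under one-lung
ventilation, and a one-sample t-test of waveform-correlation R-values
against a reference level (default 0.9).

dEELV is computed from end-expiratory CT scans at different PEEP settings as
consecutive-step quadrant air-volume differences; both dEELV and its EIT
analogue dEELI are normalized by the sum of the four regional values at the
highest PEEP setting (x100).

``run_study_replication`` wires the whole pipeline together on synthetic
animals: phantom generation, electrode detection and registration, CT
quantification (whole lung and belt slab), EIT regional analysis, waveform
NCCF, one-lung side detection and the dEELV-vs-dEELI comparison.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import belt_geometry, ct_quant, eit_analysis, phantom
from .grids import QUADRANTS, RegionLabelMask

__all__ = [
    "ComparisonResult",
    "delta_eelv",
    "normalize_to_highest_peep",
    "pearson_r",
    "relative_difference_percent",
    "bland_altman",
    "quadrant_goodness",
    "paired_side_test",
    "one_sample_t_vs",
    "run_study_replication",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement summary between two paired measurement series."""

    pearson_r: float
    bias: float
    loa_lower: float
    loa_upper: float
    goodness_score: float | None
    n_pairs: int


def relative_difference_percent(difference, reference) -> float:
    """A difference expressed as a percentage of a reference value.

    Used e.g. to report the mean absolute tidal-volume disagreement between
    two methods relative to the applied tidal volume.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * float(difference) / float(reference)


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires n >= 3 and non-zero variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError(f"need paired samples with n >= 3, got {x.size} and {y.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland-Altman parameters of y - x: (bias, lower LoA, upper LoA).

    Limits of agreement are bias +- 1.96 times the SD of the differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired values")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def quadrant_goodness(pct_a, pct_b) -> float:
    """Mean absolute difference of two four-value regional vectors."""
    a = _as_quadrant_array(pct_a)
    b = _as_quadrant_array(pct_b)
    return float(np.mean(np.abs(a - b)))


def _as_quadrant_array(v) -> np.ndarray:
    if isinstance(v, dict):
        return np.array([float(v[q]) for q in QUADRANTS])
    arr = np.asarray(v, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"expected 4 regional values, got shape {arr.shape}")
    return arr


def paired_side_test(left_shares, right_shares) -> tuple[float, float]:
    """Paired t-test of left vs right side shares: (t, two-sided p).

    Degenerate zero-variance differences are reported as t = 0, p = 1 when
    all differences are zero, otherwise as an infinite statistic with p = 0.
    """
    left = np.asarray(left_shares, dtype=float)
    right = np.asarray(right_shares, dtype=float)
    if left.size != right.size or left.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = left - right
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        return float(np.inf * np.sign(d.mean())), 0.0
    res = stats.ttest_rel(left, right)
    return float(res.statistic), float(res.pvalue)


def one_sample_t_vs(r_values, mu0: float = 0.9, ci: float = 0.95):
    """One-sample t-test of R-values against ``mu0`` with a confidence interval.

    Returns ``(t, p, (ci_lower, ci_upper))``; mean and SD are recoverable
    from the inputs, the CI is the standard t-based interval.
    """
    r = np.asarray(r_values, dtype=float)
    if r.size < 2:
        raise ValueError("need n >= 2 values")
    res = stats.ttest_1samp(r, popmean=mu0)
    sem = stats.sem(r)
    if sem == 0:
        lo = hi = float(r.mean())
        t = 0.0 if np.isclose(r.mean(), mu0) else float(np.inf * np.sign(r.mean() - mu0))
        p = 1.0 if t == 0.0 else 0.0
        return t, p, (lo, hi)
    lo, hi = stats.t.interval(ci, df=r.size - 1, loc=r.mean(), scale=sem)
    return float(res.statistic), float(res.pvalue), (float(lo), float(hi))


def delta_eelv(
    exp_scans: list[tuple[float, "ct_quant.CTVolume"]],
    mask: RegionLabelMask,
    pairing: str = "consecutive",
) -> list[dict]:
    """Quadrant end-expiratory air-volume changes across a PEEP sequence.

    ``exp_scans`` is an ordered list of ``(peep_cmH2O, end-expiratory CT)``.
    Each entry of the result describes one pair (later minus earlier in
    sequence order): ``{"peep_from", "peep_to", "delta_ml": {VL..DR}}``.
    ``pairing`` is ``"consecutive"`` (default) or ``"all"``.
    """
    if len(exp_scans) < 2:
        raise ValueError("need >= 2 end-expiratory scans with distinct PEEP values")
    if pairing not in ("consecutive", "all"):
        raise ValueError("pairing must be 'consecutive' or 'all'")
    reports = [
        (peep, ct_quant.region_air_volume(ct, mask).region_ml) for peep, ct in exp_scans
    ]
    if pairing == "consecutive":
        idx_pairs = [(i, i + 1) for i in range(len(reports) - 1)]
    else:
        idx_pairs = [
            (i, j) for i in range(len(reports)) for j in range(i + 1, len(reports))
        ]
    out = []
    for i, j in idx_pairs:
        (p_a, vols_a), (p_b, vols_b) = reports[i], reports[j]
        out.append(
            {
                "peep_from": p_a,
                "peep_to": p_b,
                "delta_ml": {q: vols_b[q] - vols_a[q] for q in QUADRANTS},
            }
        )
    return out


def normalize_to_highest_peep(values, highest_peep_values) -> np.ndarray:
    """Express four regional values as % of the highest-PEEP regional sum."""
    v = _as_quadrant_array(values)
    ref = _as_quadrant_array(highest_peep_values)
    denom = ref.sum()
    if denom <= 0:
        raise ValueError("highest-PEEP regional sum must be positive")
    return v / denom * 100.0


# ---------------------------------------------------------------------------
# Full synthetic study replication
# ---------------------------------------------------------------------------


def run_study_replication(
    spec: phantom.PhantomSpec | None = None,
    n_animals: int = 13,
    seed: int = 0,
    weight_mean_kg: float = 66.0,
    weight_sd_kg: float = 3.0,
    noise_spiro_frac: float = 0.01,
    eit_noise_frac: float = 0.01,
    n_breaths: int = 5,
    out_dir=None,
    make_plots: bool = False,
) -> dict:
    """Run the complete synthetic validation study and summarize agreement.

    For each simulated animal the 18-step protocol is generated, electrodes
    are detected and registered, and per step the pipeline reports
    spirometric vs whole-lung CT tidal volume, EIT tidal intensity vs
    belt-slab CT tidal volume, waveform NCCF, quadrant percentages for both
    modalities and the one-lung side call; across the recruitment sequence
    (D31-D37) normalized dEELV and dEELI are compared (Pearson,
    Bland-Altman, goodness scores).

    The default phantom for the replication uses a 64-cube grid at 1.5 mm
    (the same 96 mm geometry as the native-resolution phantom) to keep the
    full 13-animal study fast.  CT/EIT noise come from ``spec`` and
    ``eit_noise_frac``.  Returns a report dict; when ``out_dir`` is given,
    writes ``report.json``, ``steps.csv`` and (optionally) plots there.
    """
    if spec is None:
        spec = phantom.PhantomSpec(grid_shape=(64, 64, 64), spacing_mm=(1.5, 1.5, 1.5))
    root = np.random.default_rng(seed)
    rows: list[dict] = []
    eelv_pcts: list[np.ndarray] = []
    eeli_pcts: list[np.ndarray] = []
    goodness_scores: list[float] = []
    one_lung_left, one_lung_right = [], []
    nccf_values: list[float] = []
    eit_mask = belt_geometry.eit_quadrant_mask(grid_size=32)

    for animal in range(n_animals):
        a_seed = int(root.integers(0, 2**31 - 1))
        a_rng = np.random.default_rng(a_seed)
        weight = float(np.clip(a_rng.normal(weight_mean_kg, weight_sd_kg), 61, 70))
        side = "right" if (animal % 13) < 10 else "left"
        steps = phantom.generate_protocol(
            spec,
            weight_kg=weight,
            seed=int(a_rng.integers(0, 2**31 - 1)),
            ventilated_side=side,
            n_breaths=n_breaths,
            eit_noise_frac=eit_noise_frac,
        )

        first = steps[0]
        electrodes = belt_geometry.detect_electrodes(
            first.ct_exp, n_expected=spec.n_electrodes
        )
        transform = belt_geometry.fit_reference_transform(electrodes)
        quad_mask = belt_geometry.build_quadrant_mask(
            transform, first.ct_exp, slab_thickness_mm=spec.slab_thickness_mm
        )
        body = ct_quant.body_mask(first.ct_exp)
        quad_mask_body = quad_mask.restrict(body)

        exp_levels_by_step: dict[str, tuple[float, np.ndarray, np.ndarray]] = {}
        for sd in steps:
            tv_spiro = float(np.ptp(sd.waveform["volume_ml"].to_numpy()))
            if noise_spiro_frac > 0:
                tv_spiro *= 1.0 + float(a_rng.normal(0.0, noise_spiro_frac))
            tv_whole = ct_quant.tidal_volume(sd.ct_insp, sd.ct_exp, body)["all"]
            tv_belt = ct_quant.tidal_volume(sd.ct_insp, sd.ct_exp, quad_mask_body)
            quad_tv_ct = np.array([tv_belt[q] for q in QUADRANTS])

            wave = eit_analysis.global_waveform(sd.eit)
            seg = eit_analysis.detect_breaths(wave, sd.eit.frame_rate_hz)
            tmap = eit_analysis.tidal_image(sd.eit, seg)
            pct_eit = eit_analysis.regional_percentages(tmap, eit_mask)
            left_pct, right_pct = eit_analysis.side_shares(pct_eit)
            side_call = eit_analysis.detect_ventilated_side(left_pct, right_pct)
            eit_tidal_intensity = float(
                sum(tmap[reg].sum(dtype=np.float64) for _, reg in eit_mask.iter_regions())
            )
            r_max, lag_s = eit_analysis.nccf(
                wave,
                sd.waveform["volume_ml"].to_numpy(),
                max_lag_s=2.0,
                frame_rate_hz=sd.eit.frame_rate_hz,
            )
            ct_total = quad_tv_ct.sum()
            pct_ct = (
                dict(zip(QUADRANTS, (quad_tv_ct / ct_total * 100.0).tolist()))
                if ct_total > 0
                else dict(zip(QUADRANTS, [np.nan] * 4))
            )
            rows.append(
                {
                    "animal": animal,
                    "step_id": sd.step.step_id,
                    "peep_cmH2O": sd.step.peep_cmH2O,
                    "mode": sd.step.mode,
                    "tv_spiro_ml": tv_spiro,
                    "tv_dect_ml": tv_whole,
                    "tv_dect_belt_ml": sum(tv_belt[q] for q in QUADRANTS),
                    "eit_global_intensity": eit_tidal_intensity,
                    "nccf_r": r_max,
                    "nccf_lag_s": lag_s,
                    **{f"quadrant_pct_ct_{q}": pct_ct[q] for q in QUADRANTS},
                    **{f"quadrant_pct_eit_{q}": pct_eit[q] for q in QUADRANTS},
                    "side_call": side_call,
                    "side_true": sd.truth.ventilated_side,
                }
            )
            nccf_values.append(r_max)
            if sd.step.step_id == "D21":
                one_lung_left.append(left_pct)
                one_lung_right.append(right_pct)
            if sd.step.step_id.startswith("D3"):
                ct_exp_vols = ct_quant.region_air_volume(sd.ct_exp, quad_mask_body).region_ml
                eeli = eit_analysis.end_expiratory_levels(sd.eit, eit_mask, seg)
                exp_levels_by_step[sd.step.step_id] = (
                    sd.step.peep_cmH2O,
                    np.array([ct_exp_vols[q] for q in QUADRANTS]),
                    eeli,
                )

        # Recruitment sequence: consecutive-step deltas normalized by the
        # highest-PEEP regional sums of each modality.
        seq = [exp_levels_by_step[f"D3{j}"] for j in range(1, 8)]
        peeps = [s[0] for s in seq]
        hi = int(np.argmax(peeps))
        ct_ref, eit_ref = seq[hi][1], seq[hi][2]
        for a, b in zip(seq[:-1], seq[1:]):
            d_eelv = normalize_to_highest_peep(b[1] - a[1], ct_ref)
            d_eeli = normalize_to_highest_peep(b[2] - a[2], eit_ref)
            eelv_pcts.append(d_eelv)
            eeli_pcts.append(d_eeli)
            goodness_scores.append(quadrant_goodness(d_eelv, d_eeli))

    df = pd.DataFrame(rows)
    eelv_flat = np.concatenate(eelv_pcts)
    eeli_flat = np.concatenate(eeli_pcts)
    bias, lo, hi_loa = bland_altman(eelv_flat, eeli_flat)
    t_ncc, p_ncc, ci_ncc = one_sample_t_vs(nccf_values, mu0=0.9)
    n_correct = int((df.loc[df.step_id == "D21", "side_call"]
                     == df.loc[df.step_id == "D21", "side_true"]).sum())
    n_one_lung = int((df.step_id == "D21").sum())
    summary = {
        "n_animals": n_animals,
        "n_conditions": int(len(df)),
        "r_tv_spiro_vs_dect": pearson_r(df.tv_spiro_ml, df.tv_dect_ml),
        "r_eit_vs_dect_belt": pearson_r(df.eit_global_intensity, df.tv_dect_belt_ml),
        "nccf_mean": float(np.mean(nccf_values)),
        "nccf_sd": float(np.std(nccf_values, ddof=1)),
        "nccf_t_vs_0.9": {"t": t_ncc, "p": p_ncc, "ci95": list(ci_ncc)},
        "one_lung_side_detection": {"n_correct": n_correct, "n_total": n_one_lung},
        "eelv_vs_eeli": {
            "pearson_r": pearson_r(eelv_flat, eeli_flat),
            "bias": bias,
            "loa_lower": lo,
            "loa_upper": hi_loa,
            "goodness_mean": float(np.mean(goodness_scores)),
            "n_pairs": int(len(eelv_pcts)),
        },
    }
    if len(one_lung_left) >= 2:
        t_side, p_side = paired_side_test(one_lung_left, one_lung_right)
        summary["one_lung_paired_t"] = {"t": t_side, "p": p_side}

    report = {"summary": summary, "steps": rows}
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        df.to_csv(out / "steps.csv", index=False)
        if make_plots:
            _write_plots(df, eelv_flat, eeli_flat, out)
    return report


def _write_plots(df: pd.DataFrame, eelv: np.ndarray, eeli: np.ndarray, out) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    axes[0].scatter(df.tv_spiro_ml, df.tv_dect_ml, s=12)
    axes[0].set_xlabel("spirometric TV (ml)")
    axes[0].set_ylabel("whole-lung CT TV (ml)")
    axes[0].set_title("tidal volume")
    axes[1].scatter(eelv, eeli, s=12)
    axes[1].set_xlabel("normalized dEELV (%)")
    axes[1].set_ylabel("normalized dEELI (%)")
    axes[1].set_title("recruitment sequence")
    mean_ = (eelv + eeli) / 2
    diff = eeli - eelv
    axes[2].scatter(mean_, diff, s=12)
    bias = diff.mean()
    sd = diff.std(ddof=1)
    for y, ls in ((bias, "-"), (bias + 1.96 * sd, "--"), (bias - 1.96 * sd, "--")):
        axes[2].axhline(y, color="k", linestyle=ls, linewidth=0.8)
    axes[2].set_xlabel("mean of methods (%)")
    axes[2].set_ylabel("dEELI - dEELV (%)")
    axes[2].set_title("Bland-Altman")
    fig.tight_layout()
    fig.savefig(out / "agreement.png", dpi=120)
    plt.close(fig)
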