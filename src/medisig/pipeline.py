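"""End-to-end orchestration: simulate/ingest -> preprocess -> analyses.

``run_pipeline`` takes a :class:`PipelineConfig`, runs the enabled stages
(spectral band-power ANOVA, respiration time-frequency contrast, PLV
synchrony counting, SVM classification) on either synthetic sessions or
EDF/BDF files, and writes CSV/JSON outputs stamped with the configuration
hash and master seed. Every stage parameter defaults to the analysis
recipe's value (2-35 Hz band-pass, 200/2 uV thresholds, 64 Hz, 0.1-32 Hz
phase band, 2-s PLV windows, 500 surrogate pairs at the 0.9 quantile,
feature grids [4,32]@0.25 Hz and [0.0625,16] Hz, 10 folds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import edf as edfio
from . import preprocess as pp
from . import spectral as sp
from . import stockwell as st
from . import synchrony as syn
from .core import CONDITIONS, Recording, stable_seed
from .synthetic import SyntheticConfig, generate_session

log = logging.getLogger("medisig")


@dataclass
class PipelineConfig:
    """Complete parameterization of one pipeline run."""

    # input: either EDF paths or a synthetic cohort
    edf_paths: tuple[str, ...] = ()
    synthetic: SyntheticConfig | None = None
    n_subjects: int = 4
    sessions_per_condition: int = 1

    # stage toggles
    run_spectral: bool = True
    run_respiration: bool = True
    run_synchrony: bool = True
    run_classify: bool = True

    # preprocessing
    bandpass: tuple[float, float] = (2.0, 35.0)
    upper_uv: float = 200.0
    lower_uv: float = 2.0
    target_fs: float = 64.0
    phase_band: tuple[float, float] = (0.1, 32.0)
    resp_band: tuple[float, float] = (0.01, 20.0)
    run_ica: bool = False

    # spectral
    psd_segment_length: int = 256
    anova_unit: str = "cell-mean"

    # synchrony
    plv_window_s: float = 2.0
    phase_grid: tuple[float, float, float] = st.EEG_PHASE_GRID
    n_surrogate_pairs: int = 500
    surrogate_confidence: float = 0.9
    threshold_override: float | None = None

    # classification
    feature_grid: tuple[float, float, float] = st.EEG_FEATURE_GRID
    resp_grid: tuple[float, float, float] = st.RESP_GRID
    classify_channels: tuple[str, ...] | None = None
    folds: int = 10
    kcca_kappa: float = 0.02
    kcca_max_lag: int = 10
    kcca_max_n: int = 500
    #: optional cap on feature vectors kept per subject and modality after
    #: KCCA thinning (uniform stride); bounds the SVM problem size
    max_feature_samples: int | None = None
    sigma_factors: tuple[float, ...] = tuple(2.0 ** np.arange(-4, 5))
    c_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-2, 7))
    fold_mode: str = "blocked"
    normalization: str = "train-bounds"
    selection: str = "validation"

    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def read_session(path, resp_label: str = "Resp",
                 require_respiration: bool = True):
    """Read an EDF/BDF session into (eeg, respiration) recordings.

    Channels are mapped onto the standard montage by label; unknown
    labels are reported and left unmapped.
    """
    rec = edfio.read_edf(path)
    unknown = [c for c in rec.channel_labels
               if c not in rec.region_map and c != resp_label]
    if unknown:
        log.warning("unmapped channel labels in %s: %s", path, unknown)
    try:
        return edfio.split_session(rec, resp_label)
    except ValueError:
        if require_respiration:
            raise ValueError(
                f"no respiration channel {resp_label!r} in {path}"
            ) from None
        return rec, None


def _load_sessions(config: PipelineConfig):
    """Yield (subject, condition, session_index, eeg, resp)."""
    if config.edf_paths:
        for path in config.edf_paths:
            eeg, resp = read_session(path)
            yield (eeg.subject_id or Path(path).stem, eeg.condition, 0,
                   eeg, resp)
        return
    syn_cfg = config.synthetic or SyntheticConfig(seed=config.seed)
    for s in range(config.n_subjects):
        sid = f"s{s + 1:02d}"
        for condition in CONDITIONS:
            for k in range(config.sessions_per_condition):
                eeg, resp = generate_session(syn_cfg, sid, condition,
                                             session=k)
                yield sid, condition, k, eeg, resp


def _concat(recs: list[Recording]) -> Recording:
    if len(recs) == 1:
        return recs[0]
    return recs[0].copy_with(
        samples=np.concatenate([r.samples for r in recs], axis=1)
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; return the result bundle.

    The bundle carries per-stage outputs plus a ``status`` map; a stage
    failure is recorded (status ``error:<message>``) without aborting the
    remaining independent stages.
    """
    bundle: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "status": {},
    }
    sessions = list(_load_sessions(config))
    if not sessions:
        raise ValueError("no input sessions")
    log.info("pipeline start: %d sessions, config %s",
             len(sessions), bundle["config_hash"])

    # ---- preprocessing --------------------------------------------------
    spectral_ready, phase_ready, resp_ready = {}, {}, {}
    for sid, condition, k, eeg, resp in sessions:
        key = (sid, condition)
        try:
            prepped, mask = pp.preprocess_eeg_spectral(
                eeg, run_ica=config.run_ica,
                seed=stable_seed(config.seed, "ica", sid, condition, k),
                target_fs=config.target_fs,
                band=config.bandpass,
                upper=config.upper_uv,
                lower=config.lower_uv,
            )
            spectral_ready.setdefault(key, []).append((prepped, mask))
            phase_ready.setdefault(key, []).append(
                pp.preprocess_eeg_phase(eeg, target_fs=config.target_fs,
                                        lowcut=config.phase_band[0],
                                        highcut=config.phase_band[1])
            )
            if resp is not None:
                resp_ready.setdefault(key, []).append(
                    pp.preprocess_respiration(resp,
                                              target_fs=config.target_fs,
                                              lowcut=config.resp_band[0],
                                              highcut=config.resp_band[1])
                )
        except Exception as exc:  # noqa: BLE001 - reported per stage
            bundle["status"]["preprocess"] = f"error: {exc}"
            raise
    bundle["status"]["preprocess"] = "ok"
    log.info("preprocess done: %d subject-conditions", len(spectral_ready))

    region_map = sessions[0][3].region_map

    # ---- spectral -------------------------------------------------------
    if config.run_spectral:
        try:
            records = []
            for (sid, condition), items in spectral_ready.items():
                psds = [sp.bartlett_psd(rec, config.psd_segment_length, mask)
                        for rec, mask in items]
                power = np.mean([p.power for p in psds], axis=0)
                psd = dataclasses.replace(psds[0], power=power)
                records.append((sid, condition, psd))
            per_freq = config.anova_unit == "per-frequency"
            table = sp.cohort_power_table(records, region_map,
                                          per_frequency=per_freq)
            anova = {
                band: sp.band_power_anova(table, band, unit=config.anova_unit)
                for band in ("theta", "alpha", "beta")
            }
            bundle["power_table"] = table
            bundle["spectral_anova"] = anova
            bundle["status"]["spectral"] = "ok"
            log.info("spectral done: %d rows", len(table))
        except Exception as exc:  # noqa: BLE001
            bundle["status"]["spectral"] = f"error: {exc}"

    # ---- respiration ----------------------------------------------------
    if config.run_respiration:
        try:
            if not resp_ready:
                raise ValueError("respiration stage enabled but no "
                                 "respiration channels present")
            maps: dict = {}
            for (sid, condition), items in resp_ready.items():
                joined = _concat(items)
                maps.setdefault(sid, {})[condition] = st.stransform(
                    joined.samples[0], joined.fs, *config.resp_grid,
                    channel=f"{sid}/{condition}/resp",
                )
            contrast, spectra = st.respiration_tfa_contrast(maps)
            bundle["respiration_anova"] = contrast
            bundle["respiration_spectra"] = spectra
            bundle["status"]["respiration"] = "ok"
            log.info("respiration done: F=%.2f p=%.3g", contrast.F, contrast.p)
        except Exception as exc:  # noqa: BLE001
            bundle["status"]["respiration"] = f"error: {exc}"

    # ---- synchrony ------------------------------------------------------
    if config.run_synchrony:
        try:
            if config.threshold_override is not None:
                thr = syn.SurrogateThreshold(
                    threshold=config.threshold_override,
                    confidence=config.surrogate_confidence,
                    n_pairs=0, seed=config.seed, method="override",
                )
            else:
                ref_key = next(k for k in phase_ready if k[1] == "control")
                reference = _concat(phase_ready[ref_key]).channel("Oz")
                thr = syn.surrogate_threshold(
                    reference, fs=config.target_fs,
                    n_pairs=config.n_surrogate_pairs,
                    confidence=config.surrogate_confidence,
                    seed=stable_seed(config.seed, "surrogate"),
                    grid=config.phase_grid,
                    window_s=config.plv_window_s,
                )
            frames = []
            for (sid, condition), items in phase_ready.items():
                band_plv = syn.session_band_plv(
                    _concat(items), grid=config.phase_grid,
                    window_s=config.plv_window_s,
                )
                counts = syn.count_synchronous_pairs(band_plv, thr.threshold)
                counts.insert(0, "condition", condition)
                counts.insert(0, "subject", sid)
                frames.append(counts)
            counts = pd.concat(frames, ignore_index=True)
            summary = (counts.groupby(["condition", "band"], as_index=False)
                       ["count"].mean())
            bundle["synchrony_threshold"] = thr
            bundle["synchrony_counts"] = counts
            bundle["synchrony_summary"] = summary
            bundle["status"]["synchrony"] = "ok"
            log.info("synchrony done: threshold=%.3f", thr.threshold)
        except Exception as exc:  # noqa: BLE001
            bundle["status"]["synchrony"] = f"error: {exc}"

    # ---- classification -------------------------------------------------
    if config.run_classify:
        try:
            if not resp_ready:
                raise ValueError("classification uses respiration features "
                                 "but none are present")
            reports = classify_cohort(config, phase_ready, resp_ready)
            accs = {
                modality: float(np.mean([r.accuracy for r in by_subject.values()]))
                for modality, by_subject in reports.items()
            }
            bundle["classifier_reports"] = reports
            bundle["classifier_accuracy"] = accs
            bundle["status"]["classify"] = "ok"
            log.info("classification done: %s", accs)
        except Exception as exc:  # noqa: BLE001
            bundle["status"]["classify"] = f"error: {exc}"

    if config.out_dir:
        _write_bundle(config, bundle)
    return bundle


def _session_features(config: PipelineConfig, rec: Recording,
                      grid, channels, block_tag: str) -> cls.FeatureSet:
    tf_maps = [
        st.stransform(rec.channel(c), rec.fs, *grid, channel=c)
        for c in channels
    ]
    n = tf_maps[0].coefficients.shape[1]
    labels = np.array([rec.condition] * n)
    block = np.array([block_tag] * n)
    return cls.extract_features(tf_maps, labels=labels, block=block)


def _stack_features(parts: list[cls.FeatureSet]) -> cls.FeatureSet:
    return cls.FeatureSet(
        X=np.concatenate([p.X for p in parts], axis=0),
        labels=np.concatenate([p.labels for p in parts]),
        block=np.concatenate([p.block for p in parts]),
        frequency_grids=parts[0].frequency_grids,
        channels=parts[0].channels,
    )


def classify_cohort(config: PipelineConfig, phase_ready: dict,
                    resp_ready: dict) -> dict:
    """Per-subject EEG-only / respiration-only / joint SVM reports."""
    subjects = sorted({sid for sid, _ in phase_ready})
    reports: dict = {"eeg": {}, "respiration": {}, "joint": {}}
    for sid in subjects:
        eeg_parts, resp_parts = [], []
        for condition in CONDITIONS:
            eeg_sessions = phase_ready[(sid, condition)]
            resp_sessions = resp_ready[(sid, condition)]
            channels = config.classify_channels or eeg_sessions[0].channel_labels
            for k, (erec, rrec) in enumerate(zip(eeg_sessions, resp_sessions)):
                ef = _session_features(
                    config, erec, config.feature_grid, channels,
                    block_tag=f"{condition}/{k}",
                )
                rf = _session_features(
                    config, rrec, config.resp_grid, rrec.channel_labels,
                    block_tag=f"{condition}/{k}",
                )
                # modalities lose different filter transients; align on the
                # common time grid before stacking
                n = min(ef.n_samples, rf.n_samples)
                eeg_parts.append(ef.take(np.arange(n)))
                resp_parts.append(rf.take(np.arange(n)))
        eeg_feat = _stack_features(eeg_parts)
        resp_feat = _stack_features(resp_parts)
        joint_feat = cls.build_joint_features(eeg_feat, resp_feat)

        for modality, feat in (("eeg", eeg_feat),
                               ("respiration", resp_feat),
                               ("joint", joint_feat)):
            seed = stable_seed(config.seed, "classify", sid, modality)
            L, _curve = cls.select_downsampling_factor(
                feat, max_lag=config.kcca_max_lag, kappa=config.kcca_kappa,
                max_n=config.kcca_max_n, seed=seed,
            )
            thin = cls.downsample_features(feat, L)
            cap = config.max_feature_samples
            if cap is not None and thin.n_samples > cap:
                stride = int(np.ceil(thin.n_samples / cap))
                thin = thin.take(np.arange(0, thin.n_samples, stride))
            reports[modality][sid] = cls.train_eval_svm(
                thin,
                folds=config.folds,
                sigma_factors=np.asarray(config.sigma_factors),
                c_grid=np.asarray(config.c_grid),
                fold_mode=config.fold_mode,
                normalization=config.normalization,
                selection=config.selection,
                seed=seed,
                modality=modality,
            )
    return reports


def _write_bundle(config: PipelineConfig, bundle: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": bundle["config_hash"], "seed": config.seed}
    (out / "config.json").write_text(
        json.dumps(_jsonable(dataclasses.asdict(config)) | stamp, indent=2)
    )
    (out / "status.json").write_text(json.dumps(bundle["status"], indent=2))
    if "power_table" in bundle:
        bundle["power_table"].to_csv(out / "power_table.csv", index=False)
        (out / "spectral_anova.json").write_text(json.dumps(
            _jsonable({b: [dataclasses.asdict(r) for r in rs]
                       for b, rs in bundle["spectral_anova"].items()}) | stamp,
            indent=2))
    if "respiration_anova" in bundle:
        bundle["respiration_spectra"].to_csv(
            out / "respiration_spectra.csv", index=False)
        (out / "respiration_anova.json").write_text(json.dumps(
            _jsonable(dataclasses.asdict(bundle["respiration_anova"])) | stamp,
            indent=2))
    if "synchrony_counts" in bundle:
        bundle["synchrony_counts"].to_csv(out / "synchrony_counts.csv",
                                          index=False)
        thr = bundle["synchrony_threshold"]
        (out / "synchrony_threshold.json").write_text(json.dumps({
            "threshold": thr.threshold, "confidence": thr.confidence,
            "n_pairs": thr.n_pairs, "seed": thr.seed, "method": thr.method,
        } | stamp, indent=2))
    if "classifier_reports" in bundle:
        payload = {
            modality: {
                sid: {
                    "accuracy": r.accuracy, "sigma": r.sigma, "c": r.c,
                    "fold_accuracies": r.fold_accuracies.tolist(),
                    "decision_values": r.decision_values.tolist(),
                }
                for sid, r in by_subject.items()
            }
            for modality, by_subject in bundle["classifier_reports"].items()
        }
        (out / "classifier_report.json").write_text(json.dumps(
            {"mean_accuracy": bundle["classifier_accuracy"],
             "per_subject": payload} | stamp, indent=2))
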