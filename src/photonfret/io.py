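"""File formats: photon traces, model/detector specs, posterior dumps.

Traces are plain delimited text with ``#key=value`` header lines; model and
detector calibrations are YAML key-value files with an explicit ``unit``
field.  Everything round-trips byte-stably enough to diff and replay runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detection import DetectorModel, calibrate_from_rcm, routing_from_factors
from .inference import PosteriorSamples
from .likelihood import BinnedTrace, PhotonTrace, PulsedTrace
from .statespace import (
    BackgroundSpec,
    PhotophysicsSpec,
    SystemKinetics,
    build_composite_generator,
    efficiency_to_fret_rate,
)

__all__ = [
    "read_photon_trace",
    "write_photon_trace",
    "read_binned_trace",
    "write_binned_trace",
    "load_model",
    "load_detector",
    "summarize_posterior",
    "write_posterior",
]


def write_photon_trace(trace, path, unit="ms"):
    """Write a (pulsed or continuous) trace as two-column delimited text.

    Pulsed microtimes are stored as absolute times and reconstructed on read.
    """
    path = Path(path)
    lines = [f"#unit={unit}"]
    if isinstance(trace, PulsedTrace):
        lines += [
            "#mode=pulsed",
            f"#tau={float(trace.period)!r}",
            f"#pulse_width={float(trace.pulse_width)!r}",
            f"#n_pulses={int(trace.n_pulses)}",
        ]
        times = trace.absolute_times()
        channels = trace.channels
    else:
        lines += [
            "#mode=continuous",
            f"#tstart={float(trace.t_start)!r}",
            f"#tend={float(trace.t_end)!r}",
        ]
        times = trace.times
        channels = trace.channels
    lines.append("arrival_time\tchannel")
    for t, c in zip(times, channels):
        lines.append(f"{float(t)!r}\t{int(c) + 1}")  # channels are 1-based on disk
    path.write_text("\n".join(lines) + "\n")


def read_photon_trace(path, n_channels=2):
    """Read a trace file; returns PhotonTrace or PulsedTrace by its #mode."""
    meta = {}
    times, channels = [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
            continue
        parts = line.replace(",", "\t").split()
        if parts[0] == "arrival_time":
            continue
        try:
            t = float(parts[0])
            c = int(parts[1])
        except (IndexError, ValueError) as err:
            raise ValueError(f"{path}:{lineno}: malformed record {line!r}") from err
        if not 1 <= c <= n_channels:
            raise ValueError(f"{path}:{lineno}: unknown channel {c}")
        if times and t <= times[-1]:
            raise ValueError(
                f"{path}:{lineno}: arrival times must be strictly increasing"
            )
        times.append(t)
        channels.append(c - 1)
    mode = meta.get("mode", "continuous")
    times = np.asarray(times)
    channels = np.asarray(channels, dtype=np.int64)
    if mode == "pulsed":
        tau = float(meta["tau"])
        idx = np.floor(times / tau).astype(np.int64)
        if np.any(np.diff(idx) <= 0):
            raise ValueError(f"{path}: more than one photon in a pulse")
        n_pulses = int(meta.get("n_pulses", (idx[-1] + 1) if idx.size else 0))
        return PulsedTrace(
            period=tau,
            pulse_width=float(meta["pulse_width"]),
            n_pulses=n_pulses,
            pulse_indices=idx,
            microtimes=times - idx * tau,
            channels=channels,
        )
    t_start = float(meta.get("tstart", 0.0))
    t_end = float(meta["tend"]) if "tend" in meta else None
    return PhotonTrace(times=times, channels=channels, t_start=t_start, t_end=t_end)


def write_binned_trace(binned: BinnedTrace, path, unit="ms"):
    path = Path(path)
    header = f"#unit={unit}\n#bin_size={binned.bin_size!r}\n"
    body = "\n".join("\t".join(str(x) for x in row) for row in binned.counts)
    path.write_text(header + body + "\n")


def read_binned_trace(path) -> BinnedTrace:
    meta, rows = {}, []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        else:
            rows.append([int(x) for x in line.split()])
    return BinnedTrace(bin_size=float(meta["bin_size"]), counts=np.asarray(rows))


def load_model(path):
    """Load a model specification file.

    Returns (SystemKinetics, PhotophysicsSpec, BackgroundSpec | None, unit).
    FRET rates may be given directly (``fret_rates``) or as efficiencies
    (``fret_efficiencies``, converted through the donor relaxation rate).
    """
    spec = yaml.safe_load(Path(path).read_text())
    unit = spec.get("unit", "ms")
    system = SystemKinetics(np.asarray(spec["system_rates"], dtype=float))
    ld = float(spec["donor_relax_rate"])
    if "fret_rates" in spec:
        fret = tuple(float(x) for x in spec["fret_rates"])
    else:
        fret = tuple(
            efficiency_to_fret_rate(float(e), ld) for e in spec["fret_efficiencies"]
        )
    photo = PhotophysicsSpec(
        excitation_rate=float(spec["excitation_rate"]),
        donor_relax_rate=ld,
        acceptor_relax_rate=float(spec["acceptor_relax_rate"]),
        fret_rates=fret,
        direct_excitation_rate=float(spec.get("direct_excitation_rate", 0.0)),
        bleach_rate=float(spec.get("bleach_rate", 0.0)),
        blink_rate=float(spec.get("blink_rate", 0.0)),
        unblink_rate=float(spec.get("unblink_rate", 0.0)),
    )
    bg = None
    if "background_rates" in spec:
        bg = BackgroundSpec(tuple(float(x) for x in spec["background_rates"]))
    return system, photo, bg, unit


def build_generator_from_file(path):
    from .statespace import add_background

    system, photo, bg, unit = load_model(path)
    gen = build_composite_generator(system, photo)
    if bg is not None:
        gen = add_background(gen, bg)
    return gen


def load_detector(path) -> DetectorModel:
    """Load a detector calibration file (routing matrix or RCM, dead times,
    IRF as (delay, weight) pairs or a named truncated-gaussian)."""
    spec = yaml.safe_load(Path(path).read_text())
    if "rcm" in spec:
        routing = routing_from_factors(calibrate_from_rcm(np.asarray(spec["rcm"])))
    else:
        routing = np.asarray(spec["routing"], dtype=float)
    dead = spec.get("dead_times")
    resolution = float(spec.get("resolution", 0.0))
    irf = spec.get("irf")
    if irf is None:
        return DetectorModel(routing=routing, dead_times=dead, resolution=resolution)
    if isinstance(irf, dict) and irf.get("type") == "truncated-gaussian":
        return DetectorModel.with_truncated_gaussian_irf(
            routing=routing,
            mean=float(irf["mean"]),
            width=float(irf["width"]),
            support=float(irf["support"]),
            resolution=resolution,
            dead_times=dead,
        )
    pairs = np.asarray(irf, dtype=float)
    weights = pairs[:, 1] / pairs[:, 1].sum()
    return DetectorModel(
        routing=routing,
        dead_times=dead,
        irf_delays=pairs[:, 0],
        irf_weights=weights,
        resolution=resolution,
    )


def summarize_posterior(
    samples: PosteriorSamples | pd.DataFrame,
    donor_relax_rate: float | None = None,
    burn_in: float | None = None,
    quantiles=(0.05, 0.5, 0.95),
) -> pd.DataFrame:
    """Quantile summary (median and 5/95%) per parameter after burn-in.

    With ``donor_relax_rate`` given, FRET-rate columns additionally yield
    derived FRET-efficiency rows.
    """
    if isinstance(samples, PosteriorSamples):
        df = samples.rates
        burn_in = samples.burn_in if burn_in is None else burn_in
    else:
        df = samples
        burn_in = 0.2 if burn_in is None else burn_in
    if len(df) < 10:
        raise ValueError("need at least 10 draws to summarize")
    post = df.iloc[int(burn_in * len(df)):]
    out = {col: [post[col].quantile(q) for q in quantiles] for col in post.columns}
    if donor_relax_rate is not None:
        for col in post.columns:
            if col.startswith("fret_"):
                eff = post[col] / (post[col] + donor_relax_rate)
                out[f"efficiency_{col.split('_')[1]}"] = [
                    eff.quantile(q) for q in quantiles
                ]
    return pd.DataFrame(out, index=[f"q{int(100 * q)}" for q in quantiles]).T


def write_posterior(samples: PosteriorSamples, prefix):
    """Write draws as delimited text plus a JSON metadata sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = samples.rates.copy()
    df["log_posterior"] = samples.log_posterior
    if samples.loads is not None:
        for i in range(samples.loads.shape[1]):
            df[f"load_{i + 1}"] = samples.loads[:, i]
    df.to_csv(f"{prefix}_samples.tsv", sep="\t", index=False)
    meta = {
        "acceptance": {k: float(v) for k, v in samples.acceptance.items()},
        "burn_in": samples.burn_in,
        "n_draws": samples.n_draws,
        **{k: v for k, v in samples.meta.items() if isinstance(v, (int, float, str))},
    }
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
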