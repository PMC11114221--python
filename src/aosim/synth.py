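"""Synthetic receptor-array sensing data.

Emulates a three-channel artificial olfactory system in which each channel
is an extended-gate sensor functionalized with one human olfactory receptor
(hOR51E1, hOR51E2, hOR52D1) and read out through an organic synaptic device.
The per-channel readout is G_max, the maximum conductance reached during a
potentiation train while the sensor is exposed to an odorant stream.

The generator is parameterized by an :class:`AffinityProfile`: a channel ×
odorant matrix of mean G_max at the 3 ppm reference concentration.  The PA
column holds the measured values (170.3, 146.1, 119.6 μS); the remaining
columns are synthetic, chosen to preserve each receptor's response rank
order across the four short-chain fatty acids and an inter-class separation
of a few noise standard deviations.

Mixtures follow the equimolar 1/n rule: an n-component mixture at a given
total concentration contributes 1/n of each component's full signal, and
the mixture signal is the sum — i.e. the composition-weighted mean of the
component signals.  Concentration response is linear through the origin of
the baseline: G(c) = baseline + (G_ref − baseline) · c / 3 ppm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "ODORANTS",
    "REFERENCE_PPM",
    "AffinityProfile",
    "ResponseRecord",
    "CalibrationCurve",
    "default_affinity_profile",
    "mixture_signal",
    "expected_gmax",
    "sample_responses",
    "make_calibration",
    "records_to_frame",
    "frame_to_records",
    "write_responses",
    "read_responses",
    "composition_label",
]

CHANNELS = ("hOR51E1", "hOR51E2", "hOR52D1")
ODORANTS = ("PA", "BA", "VA", "HA")  # propionic, butyric, valeric, hexanoic acid
REFERENCE_PPM = 3.0


@dataclass(frozen=True)
class AffinityProfile:
    """Channel × odorant mean G_max matrix plus noise and baseline levels.

    ``mean_gmax[i, j]`` is the mean G_max (μS) of channel ``channels[i]``
    under odorant ``odorants[j]`` at the reference concentration (3 ppm).
    ``noise_sd`` holds the matching per-cell measurement noise SD and
    ``baseline_gmax`` the per-channel response with no odorant present.
    """

    channels: tuple = CHANNELS
    odorants: tuple = ODORANTS
    mean_gmax: np.ndarray = None
    noise_sd: np.ndarray = None
    baseline_gmax: np.ndarray = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_gmax", np.asarray(self.mean_gmax, dtype=float))
        object.__setattr__(self, "noise_sd", np.asarray(self.noise_sd, dtype=float))
        object.__setattr__(self, "baseline_gmax", np.asarray(self.baseline_gmax, dtype=float))
        nc, no = len(self.channels), len(self.odorants)
        if self.mean_gmax.shape != (nc, no) or self.noise_sd.shape != (nc, no):
            raise ValueError("mean_gmax and noise_sd must be channel x odorant matrices")
        if self.baseline_gmax.shape != (nc,):
            raise ValueError("baseline_gmax must be per-channel")
        if not np.all(np.isfinite(self.mean_gmax)):
            raise ValueError("mean_gmax matrix must be complete")
        if np.any(self.mean_gmax <= self.baseline_gmax[:, None]):
            raise ValueError("every mean_gmax must exceed its channel baseline")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be >= 0")

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None

    def odorant_index(self, odorant: str) -> int:
        try:
            return self.odorants.index(odorant)
        except ValueError:
            raise KeyError(f"unknown odorant {odorant!r}") from None

    def to_json(self) -> str:
        return json.dumps(
            {
                "channels": list(self.channels),
                "odorants": list(self.odorants),
                "mean_gmax_uS": self.mean_gmax.tolist(),
                "noise_sd_uS": self.noise_sd.tolist(),
                "baseline_gmax_uS": self.baseline_gmax.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "AffinityProfile":
        d = json.loads(text)
        return cls(
            channels=tuple(d["channels"]),
            odorants=tuple(d["odorants"]),
            mean_gmax=d["mean_gmax_uS"],
            noise_sd=d["noise_sd_uS"],
            baseline_gmax=d["baseline_gmax_uS"],
        )


# Default mean G_max matrix (μS at 3 ppm).  The PA column is measured; the
# BA/VA/HA columns are synthetic, constructed so that hOR51E1 responds most
# strongly to the shortest chain (PA > BA > VA > HA), hOR51E2 peaks at
# butyric acid (BA > VA > PA > HA) and hOR52D1 prefers the longest chain
# (HA > VA > BA > PA) — a chain-length-complementary receptor code.
_DEFAULT_MEAN_GMAX = np.array(
    [
        #  PA      BA     VA     HA
        [170.3, 155.0, 140.0, 125.0],  # hOR51E1
        [146.1, 165.0, 152.0, 128.0],  # hOR51E2
        [119.6, 134.0, 149.0, 168.0],  # hOR52D1
    ]
)
_DEFAULT_BASELINE = np.array([100.0, 100.0, 100.0])
#: default measurement noise: 4% of the ~50 μS span of mean G_max responses
_DEFAULT_NOISE_SD = 2.0


def default_affinity_profile(noise_sd: float = _DEFAULT_NOISE_SD) -> AffinityProfile:
    """Default three-receptor, four-odorant affinity profile.

    The PA column equals the measured (170.3, 146.1, 119.6) μS; the other
    columns are synthetic values preserving the per-channel rank structure
    (see module docstring).
    """
    return AffinityProfile(
        mean_gmax=_DEFAULT_MEAN_GMAX.copy(),
        noise_sd=np.full_like(_DEFAULT_MEAN_GMAX, float(noise_sd)),
        baseline_gmax=_DEFAULT_BASELINE.copy(),
    )


@dataclass(frozen=True)
class ResponseRecord:
    """One sensing measurement of one channel.

    ``composition`` maps odorant name to molar fraction (summing to 1);
    ``total_concentration`` is the total odorant level in ppm and ``gmax``
    the measured maximum conductance in μS.
    """

    sample_id: str
    composition: dict
    total_concentration: float
    channel: str
    gmax: float

    def __post_init__(self) -> None:
        fr = np.array(list(self.composition.values()), dtype=float)
        if len(fr) == 0 or np.any(fr <= 0):
            raise ValueError("composition fractions must be strictly positive")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"composition fractions must sum to 1, got {fr.sum()!r}")
        if self.total_concentration <= 0:
            raise ValueError("total_concentration must be positive")


def composition_label(composition: dict) -> str:
    """Canonical class label of a composition, e.g. ``'PA+BA'``."""
    order = {o: i for i, o in enumerate(ODORANTS)}
    names = sorted(composition, key=lambda o: order.get(o, len(order)))
    return "+".join(names)


def _format_composition(composition: dict) -> str:
    order = {o: i for i, o in enumerate(ODORANTS)}
    names = sorted(composition, key=lambda o: order.get(o, len(order)))
    return ";".join(f"{o}:{composition[o]:.6g}" for o in names)


def _parse_composition(text: str) -> dict:
    comp = {}
    for part in str(text).split(";"):
        name, _, frac = part.partition(":")
        comp[name.strip()] = float(frac)
    return comp


def mixture_signal(profile: AffinityProfile, composition: dict, channel: str) -> float:
    """Expected G_max of a mixture at the reference concentration (μS).

    Implements the equimolar 1/n sum rule in its general fraction-weighted
    form: signal = Σ_o fraction_o · mean_gmax[channel, o].  For an
    equimolar n-mixture this is the arithmetic mean of the component
    signals; it is linear in the composition vector.
    """
    fr = np.array(list(composition.values()), dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("composition fractions must sum to 1")
    ci = profile.channel_index(channel)
    return float(
        sum(f * profile.mean_gmax[ci, profile.odorant_index(o)] for o, f in composition.items())
    )


def expected_gmax(
    profile: AffinityProfile, composition: dict, total_concentration: float, channel: str
) -> float:
    """Expected G_max (μS) at an arbitrary total concentration.

    Linear concentration calibration through the channel baseline:
    G(c) = baseline + (G_ref − baseline) · c / 3 ppm, applied to the
    mixture signal at reference concentration.
    """
    if total_concentration <= 0:
        raise ValueError("total_concentration must be positive")
    ci = profile.channel_index(channel)
    base = profile.baseline_gmax[ci]
    ref = mixture_signal(profile, composition, channel)
    return float(base + (ref - base) * total_concentration / REFERENCE_PPM)


def _mixture_noise_sd(profile: AffinityProfile, composition: dict, channel: str) -> float:
    ci = profile.channel_index(channel)
    return float(
        sum(f * profile.noise_sd[ci, profile.odorant_index(o)] for o, f in composition.items())
    )


def sample_responses(
    profile: AffinityProfile,
    composition: dict,
    total_concentration: float = REFERENCE_PPM,
    n_replicates: int = 1,
    seed: int | None = 0,
    channels: tuple | None = None,
    sample_prefix: str = "s",
) -> list:
    """Draw seeded replicate measurements for every channel.

    Each record's gmax is Normal(expected_gmax, noise_sd) with the noise SD
    composition-weighted like the signal.  Records are ordered replicate by
    replicate, channel-major within a replicate, so one replicate yields
    one record per channel (a channel triple).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if total_concentration <= 0:
        raise ValueError("total_concentration must be positive")
    channels = profile.channels if channels is None else channels
    rng = np.random.default_rng(seed)
    label = composition_label(composition)
    records = []
    for r in range(n_replicates):
        for ch in channels:
            mu = expected_gmax(profile, composition, total_concentration, ch)
            sd = _mixture_noise_sd(profile, composition, ch)
            g = mu + rng.normal(0.0, sd) if sd > 0 else mu
            records.append(
                ResponseRecord(
                    sample_id=f"{sample_prefix}-{label}-{r:04d}",
                    composition=dict(composition),
                    total_concentration=total_concentration,
                    channel=ch,
                    gmax=float(g),
                )
            )
    return records


@dataclass(frozen=True)
class CalibrationCurve:
    """Concentration-response calibration of one channel-odorant pair.

    ``points`` are (concentration ppm, mean G_max μS) pairs; ``slope`` is
    the least-squares sensitivity S (μS/ppm) and ``blank_sd`` the blank
    noise σ (μS) used by the 3σ/S detection limit.
    """

    channel: str
    odorant: str
    points: tuple
    slope: float
    blank_sd: float

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("calibration requires >= 3 points")
        conc = np.array([c for c, _ in self.points], dtype=float)
        if np.any(np.diff(np.sort(conc)) <= 0):
            raise ValueError("concentrations must be distinct")
        if self.blank_sd < 0:
            raise ValueError("blank_sd must be >= 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "channel": self.channel,
                "odorant": self.odorant,
                "points": [[c, g] for c, g in self.points],
                "slope_uS_per_ppm": self.slope,
                "blank_sd_uS": self.blank_sd,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        d = json.loads(text)
        return cls(
            channel=d["channel"],
            odorant=d["odorant"],
            points=tuple((float(c), float(g)) for c, g in d["points"]),
            slope=float(d["slope_uS_per_ppm"]),
            blank_sd=float(d["blank_sd_uS"]),
        )


def make_calibration(
    profile: AffinityProfile,
    channel: str,
    odorant: str,
    concentrations=(0.5, 1.0, 2.0, 3.0, 5.0),
    noise_sd: float | None = None,
    seed: int | None = 0,
    n_blanks: int = 20,
) -> CalibrationCurve:
    """Build a seeded calibration curve for one channel-odorant pair.

    Samples one noisy measurement per concentration, fits the slope by
    ordinary least squares, and estimates the blank σ as the SD of
    ``n_blanks`` replicate blank (baseline-only) readings.
    """
    conc = np.sort(np.asarray(concentrations, dtype=float))
    if conc.size < 3:
        raise ValueError("calibration requires >= 3 concentrations")
    if np.any(conc <= 0):
        raise ValueError("calibration concentrations must be positive")
    ci = profile.channel_index(channel)
    oi = profile.odorant_index(odorant)
    sd = profile.noise_sd[ci, oi] if noise_sd is None else float(noise_sd)
    if sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    comp = {odorant: 1.0}
    mu = np.array([expected_gmax(profile, comp, c, channel) for c in conc])
    g = mu + rng.normal(0.0, sd, size=mu.size) if sd > 0 else mu
    slope, _intercept = np.polyfit(conc, g, 1)
    blanks = profile.baseline_gmax[ci] + rng.normal(0.0, sd, size=n_blanks)
    blank_sd = float(np.std(blanks, ddof=1)) if sd > 0 else 0.0
    return CalibrationCurve(
        channel=channel,
        odorant=odorant,
        points=tuple(zip(conc.tolist(), g.tolist())),
        slope=float(slope),
        blank_sd=blank_sd,
    )


# ---------------------------------------------------------------------------
# delimited-text round-tripping

_RESPONSE_COLUMNS = ["sample_id", "composition", "total_ppm", "channel", "gmax_uS"]


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "composition": [_format_composition(r.composition) for r in records],
            "total_ppm": [r.total_concentration for r in records],
            "channel": [r.channel for r in records],
            "gmax_uS": [r.gmax for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list:
    missing = [c for c in _RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    return [
        ResponseRecord(
            sample_id=str(row.sample_id),
            composition=_parse_composition(row.composition),
            total_concentration=float(row.total_ppm),
            channel=str(row.channel),
            gmax=float(row.gmax_uS),
        )
        for row in df.itertuples()
    ]


def write_responses(records, path) -> None:
    df = records_to_frame(records)
    df["total_ppm"] = df["total_ppm"].map(lambda v: f"{v:.6g}")
    df["gmax_uS"] = df["gmax_uS"].map(lambda v: f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)


def read_responses(path) -> list:
    return frame_to_records(pd.read_csv(path, sep="\t"))
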