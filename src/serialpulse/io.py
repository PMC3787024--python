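"""Plate-table parsing, run configuration and manifests.

All data files are plain CSV with one header row; times are decimal hours
from inoculation, OD is unitless.  Two plate-table dialects are supported:

* ``wide``: first column ``time_h``, then one column per well;
* ``long``: columns ``well, time_h, od``.

Run configuration is flat key-value text with sections (INI style);
unknown keys are rejected fail-fast so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .traits import ODCurve

__all__ = [
    "read_plate_table",
    "write_plate_table",
    "read_layout",
    "RunConfig",
    "write_manifest",
]


def _validate_grid(well: str, times: np.ndarray) -> None:
    if times.size < 2:
        raise ValidationError(f"well {well}: need at least 2 timepoints")
    dup = times[:-1][np.diff(times) == 0]
    if dup.size:
        raise ValidationError(f"well {well}: duplicate timepoints at t={dup[:5]} h")
    if np.any(np.diff(times) < 0):
        raise ValidationError(f"well {well}: timepoints not sorted")
    steps = np.diff(times)
    bad = np.abs(steps - np.median(steps)) > 1e-9
    if np.any(bad):
        gaps = times[1:][bad]
        raise ValidationError(
            f"well {well}: non-uniform time grid, offending timestamps {gaps[:10]} h"
        )


def read_plate_table(
    path: str | Path, dialect: str = "wide", blank_od: float = 0.0
) -> dict[str, ODCurve]:
    """Parse a plate-reader table into a mapping well -> ODCurve.

    Rejects malformed rows (with their line numbers), duplicate well/time
    pairs, and non-uniform time grids (naming the offending timestamps).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc

    if dialect == "wide":
        if df.shape[1] < 2 or df.columns[0] != "time_h":
            raise ValidationError(
                f"{path}: wide dialect needs a 'time_h' first column plus wells"
            )
        bad_rows = df.index[df.isna().any(axis=1)]
        if len(bad_rows):
            lines = [int(i) + 2 for i in bad_rows[:10]]  # +2: header + 1-indexing
            raise ValidationError(f"{path}: malformed rows at lines {lines}")
        times = df["time_h"].to_numpy(dtype=float)
        curves = {}
        for well in df.columns[1:]:
            _validate_grid(str(well), times)
            curves[str(well)] = ODCurve(
                times=times, od=df[well].to_numpy(dtype=float), blank_od=blank_od
            )
        return curves

    if dialect == "long":
        required = {"well", "time_h", "od"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"{path}: long dialect needs columns {sorted(required)}"
            )
        bad_rows = df.index[df[["well", "time_h", "od"]].isna().any(axis=1)]
        if len(bad_rows):
            lines = [int(i) + 2 for i in bad_rows[:10]]
            raise ValidationError(f"{path}: malformed rows at lines {lines}")
        if df.duplicated(subset=["well", "time_h"]).any():
            dups = df[df.duplicated(subset=["well", "time_h"])].iloc[:5]
            raise ValidationError(f"{path}: duplicate well/time rows:\n{dups}")
        curves = {}
        for well, sub in df.groupby("well", sort=True):
            sub = sub.sort_values("time_h")
            times = sub["time_h"].to_numpy(dtype=float)
            _validate_grid(str(well), times)
            curves[str(well)] = ODCurve(
                times=times, od=sub["od"].to_numpy(dtype=float), blank_od=blank_od
            )
        return curves

    raise ValidationError(f"unknown dialect {dialect!r} (use 'wide' or 'long')")


def write_plate_table(
    curves: dict[str, ODCurve], path: str | Path, dialect: str = "wide"
) -> None:
    """Serialize curves to CSV at full float precision."""
    path = Path(path)
    wells = sorted(curves)
    if dialect == "wide":
        ref = curves[wells[0]].times
        for well in wells:
            if not np.array_equal(curves[well].times, ref):
                raise ValidationError(
                    f"wide dialect needs a shared time grid; well {well} differs"
                )
        df = pd.DataFrame({"time_h": ref})
        for well in wells:
            df[well] = curves[well].od
    elif dialect == "long":
        frames = [
            pd.DataFrame({"well": well, "time_h": c.times, "od": c.od})
            for well, c in ((w, curves[w]) for w in wells)
        ]
        df = pd.concat(frames, ignore_index=True)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False)


LAYOUT_COLUMNS = ["well", "species", "pulse", "diversity", "week", "replicate", "clone"]


def read_layout(path: str | Path) -> pd.DataFrame:
    """Plate layout mapping wells to treatment metadata."""
    df = pd.read_csv(path)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: layout lacks columns {missing}")
    if df["well"].duplicated().any():
        raise ValidationError(f"{path}: duplicate wells in layout")
    return df


@dataclass
class RunConfig:
    """Pipeline configuration, round-trippable through an INI file."""

    master_seed: int = 0
    output_dir: str = "results"
    # design
    n_replicates: int = 3
    n_clones: int = 10
    # assay
    duration_h: float = 168.0
    sample_interval_min: float = 5.0
    od_noise_sd: float = 0.01
    blank_od: float = 0.05
    dead_cell_opacity: float = 0.5
    medium_R: float = 1.0
    # extraction
    window_points: int = 30
    log_mode: bool = True
    smooth_width: int = 5
    end_samples: int = 12
    # stats
    alpha: float = 0.05
    family_size: int = 4

    _SECTIONS = {
        "run": ["master_seed", "output_dir"],
        "design": ["n_replicates", "n_clones"],
        "assay": ["duration_h", "sample_interval_min", "od_noise_sd", "blank_od",
                  "dead_cell_opacity", "medium_R"],
        "extraction": ["window_points", "log_mode", "smooth_width", "end_samples"],
        "stats": ["alpha", "family_size"],
    }

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"no such config file: {path}")
        parser = configparser.ConfigParser()
        parser.optionxform = str  # keys are case-sensitive
        parser.read(path)
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for section in parser.sections():
            if section not in cls._SECTIONS:
                raise ConfigError(f"{path}: unknown config section [{section}]")
            for key, raw in parser.items(section):
                if key not in cls._SECTIONS[section]:
                    raise ConfigError(f"{path}: unknown key '{key}' in [{section}]")
                typ = types[key]
                if typ in ("bool", bool):
                    kwargs[key] = raw.strip().lower() in ("1", "true", "yes", "on")
                elif typ in ("int", int):
                    kwargs[key] = int(raw)
                elif typ in ("float", float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        parser = configparser.ConfigParser()
        parser.optionxform = str
        for section, keys in self._SECTIONS.items():
            parser[section] = {k: str(getattr(self, k)) for k in keys}
        with open(path, "w") as fh:
            parser.write(fh)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(path: str | Path, config: RunConfig | dict, seed: int) -> dict:
    """Write the reproducibility manifest (config + seed + versions)."""
    import scipy

    from . import __version__

    manifest = {
        "seed": int(seed),
        "config": config.as_dict() if isinstance(config, RunConfig) else dict(config),
        "versions": {
            "serialpulse": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
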