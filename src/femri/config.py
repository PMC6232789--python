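"""Flat key=value run configuration.

Every tunable of every stage lives in one flat namespace (``mri.noise_sd``,
``watershed.min_density``, ...), read from a plain text file of ``key =
value`` lines with ``#`` comments.  Unknown keys are rejected, and each run
echoes its fully resolved configuration next to the outputs, so every
default in effect is visible and auditable in one file.
"""

from __future__ import annotations

from pathlib import Path

from .exceptions import ConfigurationError

__all__ = ["KNOWN_KEYS", "RunConfig"]


def _bool(text: str) -> bool:
    low = str(text).strip().lower()
    if low in ("1", "true", "yes", "on"):
        return True
    if low in ("0", "false", "no", "off"):
        return False
    raise ConfigurationError(f"not a boolean: {text!r}")


#: key -> (type, default)
KNOWN_KEYS: dict[str, tuple] = {
    "seed": (int, 0),
    "outdir": (str, "femri_out"),
    "pipeline": (str, "both"),  # mri | histo | both
    "log_level": (str, "INFO"),
    # MRI phantom
    "mri.grid_rows": (int, 256),
    "mri.grid_cols": (int, 256),
    "mri.pixel_size": (float, 0.1),
    "mri.tumor_radius": (float, 50.0),
    "mri.n_deposits": (int, 30),
    "mri.deposit_area_mean": (float, 4.0),
    "mri.baseline_iron_mean": (float, 0.03),
    "mri.baseline_iron_sd": (float, 0.01),
    "mri.deposit_iron_lo": (float, 0.15),
    "mri.deposit_iron_hi": (float, 0.30),
    "mri.calibration_slope": (float, 400.0),
    "mri.calibration_intercept": (float, 20.0),
    "mri.s0": (float, 100.0),
    "mri.noise_sd": (float, 0.01),
    "mri.rician": (_bool, False),
    # relaxometry
    "relax.min_signal_fraction": (float, 0.05),
    "relax.method": (str, "nls"),
    # calibration / stratification
    "cal.conc_lo": (float, 0.0),
    "cal.conc_hi": (float, 0.3),
    "cal.standards_csv": (str, ""),
    # cluster analysis
    "clusters.connectivity": (int, 8),
    "clusters.n_bins": (int, 15),
    "clusters.min_pixels": (int, 1),
    # histology phantom
    "histo.section_rows": (int, 4000),
    "histo.section_cols": (int, 4000),
    "histo.microns_per_pixel": (float, 1.0),
    "histo.n_deposits": (int, 20),
    "histo.cells_per_deposit_mean": (float, 14.0),
    "histo.n_background_macrophages": (int, 5000),
    "histo.p_m1": (float, 0.42),
    "histo.p_m2": (float, 0.58),
    "histo.p_double": (float, 0.0),
    "histo.p_iron_background": (float, 0.0041),
    # histology processing
    "detect.blue_ratio_threshold": (float, 0.5),
    "detect.luminance_cutoff": (float, 200.0),
    "downsample.factor": (int, 100),
    "watershed.sigma": (float, 1.0),
    "watershed.min_density": (float, 0.01),
    "watershed.min_area": (int, 1),
    # power simulation
    "power.n_replicates": (int, 25),
    "power.n_subjects": (int, 8),
    "power.control_deposit_mean": (float, 235 / 8),
    "power.treated_deposit_mean": (float, 748 / 8),
}


class RunConfig:
    """Validated flat configuration with defaults for every stage."""

    def __init__(self, overrides: dict | None = None):
        self._values = {key: default for key, (_, default) in KNOWN_KEYS.items()}
        for key, value in (overrides or {}).items():
            self.set(key, value)

    def set(self, key: str, value) -> None:
        if key not in KNOWN_KEYS:
            raise ConfigurationError(f"unknown configuration key: {key!r}")
        caster, _ = KNOWN_KEYS[key]
        try:
            self._values[key] = caster(value)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"bad value for {key!r}: {value!r}") from exc

    def __getitem__(self, key: str):
        if key not in KNOWN_KEYS:
            raise ConfigurationError(f"unknown configuration key: {key!r}")
        return self._values[key]

    def section(self, prefix: str) -> dict:
        """All keys under ``prefix.`` with the prefix stripped."""
        skip = len(prefix) + 1
        return {
            key[skip:]: value
            for key, value in self._values.items()
            if key.startswith(prefix + ".")
        }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        overrides = {}
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            overrides[key] = value
        return cls(overrides)

    def write(self, path) -> None:
        """Echo the fully resolved configuration as key = value lines."""
        lines = [f"{key} = {self._values[key]}" for key in sorted(self._values)]
        Path(path).write_text("\n".join(lines) + "\n")

    def as_dict(self) -> dict:
        return dict(self._values)
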