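"""Exception hierarchy for the muoct package."""


class MuoctError(Exception):
    """Base class for all muoct errors."""


class ConfigError(MuoctError, ValueError):
    """Invalid simulator or analysis configuration."""


class SidecarError(MuoctError, KeyError):
    """Calibration sidecar is missing or malformed."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class LayerError(MuoctError, RuntimeError):
    """Layer interfaces could not be resolved."""


class DynamicsError(MuoctError, RuntimeError):
    """Ciliary dynamics could not be quantified."""


class ArcError(DynamicsError):
    """No arc-like effective-stroke pattern could be fitted."""


class TrackError(MuoctError, RuntimeError):
    """Inclusion tracking failed or a track is unusable."""
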