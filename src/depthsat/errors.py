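"""Exception hierarchy for depthsat."""


class DepthSatError(Exception):
    """Base class for all depthsat errors."""


class ConfigError(DepthSatError):
    """Invalid configuration value (bad proportions, thresholds, law names...)."""


class TableParseError(DepthSatError):
    """Malformed input table; message names the offending line when known."""


class PairingError(DepthSatError):
    """A pairing of expression vectors is empty or too small to analyse."""
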