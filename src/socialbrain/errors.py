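"""Exception hierarchy.

ConfigError: a run/simulation configuration is invalid.
DataError: the data handed to an operation cannot support it
    (too short, all-censored, zero variance, ...).
AnalysisError: a statistical procedure cannot proceed
    (rank deficiency, matching impossible, degenerate variance).
"""


class SocialBrainError(Exception):
    pass


class ConfigError(SocialBrainError, ValueError):
    pass


class DataError(SocialBrainError, ValueError):
    pass


class AnalysisError(SocialBrainError, RuntimeError):
    pass
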