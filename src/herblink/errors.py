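"""Exception types with a stable exit-code contract for the CLI."""


class HerblinkError(Exception):
    """Base class; `exit_code` drives the CLI contract (2 config, 3 data)."""

    exit_code = 1


class ConfigError(HerblinkError):
    """Invalid configuration: bad threshold, unknown algorithm, invalid spec."""

    exit_code = 2


class DataError(HerblinkError):
    """Invalid input data."""

    exit_code = 3


class InputError(DataError):
    """Malformed input records (duplicates, bad fields)."""


class RoleViolationError(DataError):
    """An edge connects nodes of the wrong roles for its layer."""


class UndefinedSimilarityError(DataError):
    """Tanimoto similarity of two empty fingerprints is undefined."""


class InvalidSpecError(ConfigError):
    """A dataset spec that is not one of the three valid layer sets."""


class UndefinedMetricError(DataError):
    """A ranking metric evaluated on a single-class label vector."""


class LookupError_(DataError):
    """A node referenced by a record is missing from the metadata table."""
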