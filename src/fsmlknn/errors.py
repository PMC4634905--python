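"""Exception hierarchy for fsmlknn."""


class FSMLKNNError(Exception):
    """Base class for all fsmlknn errors."""


class ValidationError(FSMLKNNError):
    """Input data violates a structural contract (non-binary cells, duplicate ids, shape mismatch)."""


class AlignmentError(FSMLKNNError):
    """Drug identifiers of feature and label tables cannot be reconciled."""


class ConfigurationError(FSMLKNNError):
    """A parameter value is outside its valid range (e.g. k >= n)."""


class UndefinedMetricError(FSMLKNNError):
    """A metric is undefined for the given truth matrix (e.g. AUPR with zero positives)."""


class LeakageError(FSMLKNNError):
    """A test drug was found inside a training structure during cross-validation."""
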