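"""Exception hierarchy for the facematch package."""


class FacematchError(Exception):
    """Base class for all package-specific errors."""


class ManifestError(FacematchError):
    """A manifest or rating table violates a structural invariant."""


class DimensionError(FacematchError):
    """Embedding matrix shape is inconsistent with the record collection."""


class ConfigError(FacematchError):
    """A generator / pipeline configuration is invalid."""


class FeaturelessImageError(FacematchError):
    """An image carries no non-DC signal and cannot be embedded."""
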