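"""Exception hierarchy for the vesselprox pipeline."""


class VesselProxError(Exception):
    """Base class for all vesselprox errors."""


class GeometryError(VesselProxError):
    """Volume shapes or voxel sizes are incompatible."""


class ParameterError(VesselProxError, ValueError):
    """A parameter is outside its valid range."""


class InputError(VesselProxError, ValueError):
    """An input collection is missing or malformed."""


class VolumeIOError(VesselProxError, OSError):
    """A volume file could not be read or written."""


class DegenerateInputError(VesselProxError):
    """The input is valid but carries no usable signal (constant volume,
    empty organ mask, all-true or all-false segment)."""


class EmptySegmentError(DegenerateInputError):
    """A binary mask that must be nonempty contains no true voxels."""


class ResourceError(VesselProxError):
    """The requested operation would exceed the declared working-set budget."""


class SampleSizeError(VesselProxError):
    """Too few samples per group for the requested statistic."""


class ConsistencyError(VesselProxError):
    """Cross-sample bookkeeping failed (missing evaluation, bad group map)."""


class ConfigError(VesselProxError):
    """Pipeline configuration failed validation.

    Carries *every* failure found, not just the first.
    """

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))
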