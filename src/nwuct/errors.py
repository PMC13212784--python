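"""Exception hierarchy for the NWU pipeline.

Every stage raises a subclass of :class:`NWUError` so that the pipeline driver
can report which stage failed while still letting callers catch narrowly.
"""


class NWUError(Exception):
    """Base class for all pipeline errors."""


class VolumeIOError(NWUError, OSError):
    """Reading or writing a NIfTI file failed (missing file, corrupt header, ...)."""


class VolumeFormatError(NWUError, ValueError):
    """The image exists but violates the expected format (4D, non-finite, ...)."""


class RegistrationError(NWUError, RuntimeError):
    """Affine or deformable registration failed (no overlap, divergence)."""


class EmptyMaskError(NWUError, ValueError):
    """An operation that requires a non-empty mask received an empty one."""


class KernelError(NWUError, ValueError):
    """Pooling kernel incompatible with the volume (even size, larger than grid)."""


class NWUDomainError(NWUError, ValueError):
    """NWU is undefined: the contralateral (denominator) mean HU is not positive."""


class DegenerateHistogramError(NWUError, ValueError):
    """Otsu thresholding received a constant (single-valued) sample."""


class DisjointValidityError(NWUError, ValueError):
    """The two pooled hemisphere fields share no valid voxel."""


class PhantomGeometryError(NWUError, ValueError):
    """A phantom specification could not be realized (lesion crosses the midplane,
    or no admissible lesion placement was found within the retry budget)."""
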