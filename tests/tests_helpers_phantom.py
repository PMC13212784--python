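"""Helper constructors shared across test modules."""
from conftest import small_spec

from nwuct.phantom import generate_phantom


def noise_free_lesion_case(uptake: float = 10.0, side: str = "left"):
    sign = -1.0 if side == "left" else 1.0
    spec = small_spec(uptake_percent=uptake, noise_sigma=0.0,
                      lesion_center=(sign * 11.0, 1.0, 0.0),
                      lesion_radii=(8.0, 12.0, 10.0), seed=9)
    return generate_phantom(spec)
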