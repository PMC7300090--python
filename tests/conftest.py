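import numpy as np
import pytest

from stromaquant.core_io import AnalysisConfig, Modality, RasterImage


@pytest.fixture
def config():
    return AnalysisConfig()


def hsv_image(hue_deg, sat=0.9, val=1.0, modality=Modality.PSR):
    """Build a RasterImage from a 2-D array of hues (degrees)."""
    from skimage.color import hsv2rgb

    hue = np.asarray(hue_deg, dtype=np.float64)
    hsv = np.stack(
        [hue / 360.0, np.full_like(hue, sat), np.full_like(hue, val)], axis=-1
    )
    return RasterImage(np.clip(hsv2rgb(hsv), 0, 1), modality=modality)
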