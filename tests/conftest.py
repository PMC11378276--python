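import base64
import struct
import zlib

import numpy as np
import pytest

from naquant import SimulationParams, make_design, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """18-sample simulated set (6 levels x 3 replicates), mild noise."""
    design = make_design(levels=[1.0, 5.0, 10.0, 20.0, 30.0, 40.0], replicates=3)
    params = SimulationParams(
        seed=7, sigma_ppm=1.0, intensity_cv=0.05, n_baseline_peaks=20
    )
    spectra, y = simulate_dataset(design, params)
    return spectra, y


def _b64(values, dtype="d", compress=False):
    raw = struct.pack("<" + dtype * len(values), *values)
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode()


def write_mzml(path, scans, mode="centroid", compress=False, dtype="d"):
    """Write a minimal but valid-enough mzML document for the reader."""
    mode_cv = {
        "centroid": '<cvParam accession="MS:1000127" name="centroid spectrum"/>',
        "profile": '<cvParam accession="MS:1000128" name="profile spectrum"/>',
        "none": "",
    }[mode]
    dtype_acc = "MS:1000523" if dtype == "d" else "MS:1000521"
    comp_cv = (
        '<cvParam accession="MS:1000574" name="zlib compression"/>'
        if compress
        else '<cvParam accession="MS:1000576" name="no compression"/>'
    )
    blocks = []
    for mz, inten in scans:
        blocks.append(
            f"""<spectrum index="0" defaultArrayLength="{len(mz)}">
  {mode_cv}
  <binaryDataArrayList count="2">
    <binaryDataArray>
      <cvParam accession="{dtype_acc}" name="float"/>{comp_cv}
      <cvParam accession="MS:1000514" name="m/z array"/>
      <binary>{_b64(mz, dtype, compress)}</binary>
    </binaryDataArray>
    <binaryDataArray>
      <cvParam accession="{dtype_acc}" name="float"/>{comp_cv}
      <cvParam accession="MS:1000515" name="intensity array"/>
      <binary>{_b64(inten, dtype, compress)}</binary>
    </binaryDataArray>
  </binaryDataArrayList>
</spectrum>"""
        )
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml">\n'
        f'<run><spectrumList count="{len(scans)}">\n'
        + "\n".join(blocks)
        + "\n</spectrumList></run></mzML>\n"
    )
    path.write_text(doc)
    return path
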