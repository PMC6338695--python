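import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from toxscreen import SpectralLibrary, Spectrum, generate_library
from toxscreen.library import CompoundRecord, build_entry
from toxscreen.synthetic import (AnalyteProfile, FragmentTemplate,
                                 generate_breakdown_spectra)

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def random_ms2_spectrum(rng: np.random.Generator, n_peaks: int = 12,
                        scan_id: str = "s") -> Spectrum:
    """A random but structurally valid MS2 spectrum."""
    mz = np.sort(rng.uniform(50.0, 690.0, size=n_peaks))
    # enforce centroid separation so spectra are unambiguous peak lists
    mz += np.arange(n_peaks) * 0.05
    return Spectrum(
        mz=mz, intensities=rng.uniform(1.0, 1e4, size=n_peaks),
        precursor_mz=float(rng.uniform(100.0, 700.0)),
        retention_time=float(rng.uniform(0.0, 600.0)),
        collision_energy=float(rng.choice([5, 15, 25, 35, 45])),
        ms_level=2, scan_id=scan_id)


@pytest.fixture(scope="session")
def seeded_library() -> tuple[SpectralLibrary, dict]:
    """A 20-compound synthetic reference library with ground truth."""
    return generate_library(20, seed=11)


def designed_profile(cid: str, precursor: float, height: float,
                     rt_apex: float = 60.0, logp: float = 2.0,
                     n_fragments: int = 4) -> AnalyteProfile:
    """Analyte with deterministic, well-separated fragments."""
    fragments = tuple(
        FragmentTemplate(mz=80.0 + 31.7 * k, appearance_ce=8.0 + 4.0 * k,
                         max_rel_intensity=0.4 + 0.12 * k)
        for k in range(n_fragments))
    compound = CompoundRecord(name=f"analyte-{cid}", precursor_mz=precursor,
                              compound_id=cid, logp=logp)
    return AnalyteProfile(compound=compound, fragments=fragments,
                          rt_apex=rt_apex, rt_width=4.0,
                          height_per_ng_ml=height)


def entry_for(profile: AnalyteProfile, seed: int = 5):
    return build_entry(profile.compound,
                       generate_breakdown_spectra(profile, seed=seed))
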