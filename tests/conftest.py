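import csv

import pytest

from betalains.catalog import bundled_catalog, bundled_catalog_path, bundled_neutral_losses
from betalains.simulate import SimConfig


@pytest.fixture(scope="session")
def catalog():
    return bundled_catalog()


@pytest.fixture(scope="session")
def loss_table():
    return bundled_neutral_losses()


@pytest.fixture(scope="session")
def catalog_rows():
    """Raw fixture rows as dicts of strings, independent of the data model."""
    with open(bundled_catalog_path(), encoding="utf-8") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))


@pytest.fixture
def noiseless_cfg():
    """Simulation config with every noise source switched off."""
    return SimConfig(
        ppm_jitter_sd=0.0,
        fragment_mz_jitter_sd=0.0,
        rt_jitter_sd=0.0,
        n_noise_peaks_per_spectrum=0,
        seed=0,
    )


@pytest.fixture
def catalog_tsv_header():
    return (
        "id\tprinted_label\tname\tcategory\tclass\tformula\trt_min\t"
        "relative_rt\ttheoretical_mz\tobserved_mz\tppm\tfragments\t"
        "tentative\treference\n"
    )


@pytest.fixture
def tiny_catalog_tsv(tmp_path, catalog_tsv_header):
    """A two-record catalog file (betanin + isobetanin)."""
    frag = "389.09;345.10;194.04;150.05"
    body = (
        f"1\t1\tBetanin\tbetacyanin\tbetanin-type\tC24H26N2O13\t3.43\t1\t"
        f"551.1508\t551.1483\t-4.54\t{frag}\t0\t\n"
        f"2\t2\tIsobetanin\tbetacyanin\tbetanin-type\tC24H26N2O13\t6.59\t1.92\t"
        f"551.1508\t551.1481\t-4.9\t{frag}\t0\t\n"
    )
    path = tmp_path / "tiny_catalog.tsv"
    path.write_text(catalog_tsv_header + body, encoding="utf-8")
    return path
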