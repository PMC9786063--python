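import datetime
from pathlib import Path

import pytest

from pvsignal.model_io import Product, Report, ReportSet, load_vocabulary
from pvsignal.preprocess import default_catalog

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def fixture_csv() -> Path:
    return DATA_DIR / "reports_3row.csv"


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def vocab15():
    return load_vocabulary(DATA_DIR / "vocabulary.csv")


def make_report(
    case_id="C1",
    suspects=(("DrugA", "druga"),),
    concomitants=(),
    reactions=("Headache",),
    sex="female",
    age=50.0,
    reporter="consumer",
    country="US",
    date=datetime.date(2022, 6, 1),
    outcomes=(),
) -> Report:
    products = [
        Product(name=n, active_ingredient=i, role="suspected") for n, i in suspects
    ]
    products += [Product(name=n, role="concomitant") for n in concomitants]
    return Report(
        case_id=case_id,
        products=products,
        reactions=list(reactions),
        sex=sex,
        age_years=age,
        reporter_type=reporter,
        country=country,
        event_date=date,
        outcomes=frozenset(outcomes),
    )


@pytest.fixture
def four_report_set() -> ReportSet:
    """Reports (A,{x}), (A,{y}), (B,{x}), (B,{y}) on catalogued drugs."""
    reports = [
        make_report("C1", (("Remdesivir", "remdesivir"),), reactions=("x",)),
        make_report("C2", (("Remdesivir", "remdesivir"),), reactions=("y",)),
        make_report("C3", (("Sotrovimab", "sotrovimab"),), reactions=("x",)),
        make_report("C4", (("Sotrovimab", "sotrovimab"),), reactions=("y",)),
    ]
    return ReportSet(reports=reports)
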