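import pytest

from dxrank import CooccurrenceModel, MedicalRecord


@pytest.fixture
def toy_records():
    """Four-record corpus with two diseases over three symptoms, small
    enough that every count and score is checkable by hand."""
    return [
        MedicalRecord("A", ("s1", "s2"), "r1"),
        MedicalRecord("A", ("s1", "s3"), "r2"),
        MedicalRecord("B", ("s2", "s3"), "r3"),
        MedicalRecord("B", ("s3",), "r4"),
    ]


@pytest.fixture
def toy_model(toy_records):
    return CooccurrenceModel.fit(toy_records)


def write_tsv(path, rows, header=("disease", "symptoms", "source_id")):
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
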