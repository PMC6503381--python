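from pathlib import Path

import pytest

from chemcurate.resolvers import FixtureBackend, ResolverGateway


def write_registry(directory: Path, tables: dict, synonyms: dict | None = None):
    """Write fixture TSVs from {source_file: [(kind, identifier, smiles), ...]}.

    ``tables`` keys are 'cir', 'comptox', 'pubchem', 'chemid'; ``synonyms``
    maps CAS -> list of synonyms.
    """
    directory.mkdir(parents=True, exist_ok=True)
    for source in ("cir", "comptox", "pubchem", "chemid"):
        rows = tables.get(source, [])
        with (directory / f"{source}.tsv").open("w", encoding="utf-8") as fh:
            fh.write("IDENTIFIER_KIND\tIDENTIFIER\tSMILES\n")
            for kind, identifier, smiles in rows:
                fh.write(f"{kind}\t{identifier}\t{smiles}\n")
    with (directory / "synonyms.tsv").open("w", encoding="utf-8") as fh:
        fh.write("CAS\tSYNONYM\n")
        for cas, entries in (synonyms or {}).items():
            for syn in entries:
                fh.write(f"{cas}\t{syn}\n")
    return directory


@pytest.fixture
def registry_factory(tmp_path):
    def factory(tables, synonyms=None, name="registry"):
        return write_registry(tmp_path / name, tables, synonyms)

    return factory


@pytest.fixture
def gateway_factory(registry_factory):
    def factory(tables, synonyms=None):
        directory = registry_factory(tables, synonyms)
        return ResolverGateway(backend=FixtureBackend(directory))

    return factory
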