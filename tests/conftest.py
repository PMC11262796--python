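import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fluxshift.model import MetabolicModel, Metabolite, Reaction
from fluxshift.synthetic import build_toy_network


@pytest.fixture(scope="session")
def toy_model() -> MetabolicModel:
    return build_toy_network()


def linear_chain_model() -> MetabolicModel:
    """source ->A (ub 10), A->B (ub 1000), B-> sink (ub 5)."""
    return MetabolicModel(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("SRC", {"A": 1}, 0, 10),
            Reaction("AB", {"A": -1, "B": 1}, 0, 1000),
            Reaction("SNK", {"B": -1}, 0, 5),
        ],
    )


def parallel_routes_model(n_routes: int = 2, total: float = 1.0) -> MetabolicModel:
    """n parallel A->B routes sharing a fixed total flux (the n-1 simplex)."""
    reactions = [Reaction("SRC", {"A": 1}, total, total)]
    reactions += [
        Reaction(f"R{i + 1}", {"A": -1, "B": 1}, 0, total)
        for i in range(n_routes)
    ]
    reactions.append(Reaction("SNK", {"B": -1}, 0, 1000))
    return MetabolicModel(
        metabolites=[Metabolite("A"), Metabolite("B")], reactions=reactions
    )


@pytest.fixture
def chain_model() -> MetabolicModel:
    return linear_chain_model()


@pytest.fixture
def simplex_model() -> MetabolicModel:
    return parallel_routes_model(3)


# ---------------------------------------------------------------------------
# small SBML fixture documents, generated as text (both GPR dialects)
# ---------------------------------------------------------------------------

SBML_L3_FBC = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="toy3" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
      <species id="B" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb_zero" value="0" constant="true"/>
      <parameter id="ub_ten" value="10" constant="true"/>
      <parameter id="ub_big" value="1000" constant="true"/>
      <parameter id="lb_neg" value="-1000" constant="true"/>
    </listOfParameters>
    <fbc:listOfGeneProducts>
      <fbc:geneProduct fbc:id="g1" fbc:label="g1"/>
      <fbc:geneProduct fbc:id="g2" fbc:label="g2"/>
      <fbc:geneProduct fbc:id="g3" fbc:label="g3"/>
    </fbc:listOfGeneProducts>
    <listOfReactions>
      <reaction id="SRC" reversible="false" fast="false"
                fbc:lowerFluxBound="lb_zero" fbc:upperFluxBound="ub_ten">
        <listOfProducts>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="AB" reversible="true" fast="false"
                fbc:lowerFluxBound="lb_neg" fbc:upperFluxBound="ub_big">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="2" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:and>
            <fbc:geneProductRef fbc:geneProduct="g1"/>
            <fbc:or>
              <fbc:geneProductRef fbc:geneProduct="g2"/>
              <fbc:geneProductRef fbc:geneProduct="g3"/>
            </fbc:or>
          </fbc:and>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="SNK" reversible="false" fast="false"
                fbc:lowerFluxBound="lb_zero" fbc:upperFluxBound="ub_big">
        <listOfReactants>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

SBML_L2_NOTES = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="toy2">
    <listOfCompartments>
      <compartment id="c"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c"/>
      <species id="B" compartment="c"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="SRC" reversible="false">
        <listOfProducts>
          <speciesReference species="A"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <ci> FLUX_VALUE </ci>
          </math>
          <listOfParameters>
            <parameter id="LOWER_BOUND" value="0"/>
            <parameter id="UPPER_BOUND" value="10"/>
            <parameter id="FLUX_VALUE" value="0"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
      <reaction id="AB" reversible="false">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>GENE_ASSOCIATION: g1 and (g2 or g3)</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="A"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B"/>
        </listOfProducts>
      </reaction>
      <reaction id="SNK" reversible="false">
        <listOfReactants>
          <speciesReference species="B"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

SBML_BAD_SPECIES_REF = SBML_L2_NOTES.replace(
    '<speciesReference species="B"/>\n        </listOfReactants>\n      </reaction>\n    </listOfReactions>',
    '<speciesReference species="MISSING"/>\n        </listOfReactants>\n      </reaction>\n    </listOfReactions>',
)


@pytest.fixture
def sbml_l3_path(tmp_path):
    path = tmp_path / "toy_l3.xml"
    path.write_text(SBML_L3_FBC, encoding="utf-8")
    return path


@pytest.fixture
def sbml_l2_path(tmp_path):
    path = tmp_path / "toy_l2.xml"
    path.write_text(SBML_L2_NOTES, encoding="utf-8")
    return path


@pytest.fixture
def sbml_bad_ref_path(tmp_path):
    path = tmp_path / "toy_bad.xml"
    path.write_text(SBML_BAD_SPECIES_REF, encoding="utf-8")
    return path
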