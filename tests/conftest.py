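import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

from gatekeepr import fixture


@pytest.fixture
def toggle():
    return fixture("toggle")


@pytest.fixture
def negator():
    return fixture("negator")


@pytest.fixture
def bottleneck12():
    return fixture("bottleneck12")


SBML_QUAL_NOT = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:qual="http://www.sbml.org/sbml/level3/version1/qual/version1"
      level="3" version="1" qual:required="true">
  <model id="negation_wire">
    <qual:listOfQualitativeSpecies>
      <qual:qualitativeSpecies qual:id="X" qual:maxLevel="1"
            qual:initialLevel="1" qual:constant="false"/>
      <qual:qualitativeSpecies qual:id="Y" qual:maxLevel="1"
            qual:constant="false"/>
    </qual:listOfQualitativeSpecies>
    <qual:listOfTransitions>
      <qual:transition qual:id="t_Y">
        <qual:listOfInputs>
          <qual:input qual:qualitativeSpecies="X"
                qual:transitionEffect="none"/>
        </qual:listOfInputs>
        <qual:listOfOutputs>
          <qual:output qual:qualitativeSpecies="Y"
                qual:transitionEffect="assignmentLevel"/>
        </qual:listOfOutputs>
        <qual:listOfFunctionTerms>
          <qual:functionTerm qual:resultLevel="1">
            <math xmlns="http://www.w3.org/1998/Math/MathML">
              <apply><not/><apply><eq/><ci>X</ci><cn type="integer">1</cn></apply></apply>
            </math>
          </qual:functionTerm>
          <qual:defaultTerm qual:resultLevel="0"/>
        </qual:listOfFunctionTerms>
      </qual:transition>
    </qual:listOfTransitions>
  </model>
</sbml>
"""


@pytest.fixture
def sbml_not_document():
    """Two species X, Y with the single transition Y := NOT X."""
    return SBML_QUAL_NOT
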