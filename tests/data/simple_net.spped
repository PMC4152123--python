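<?xml version="1.0" encoding="UTF-8"?>
<Snoopy version="2" revision="1.13">
  <netclass name="Petri Net"/>
  <nodeclasses count="3">
    <nodeclass count="2" name="Place">
      <node id="1" net="1">
        <attribute name="Name" type="String">glucose</attribute>
        <attribute name="Marking" type="Integer">3</attribute>
      </node>
      <node id="2" net="1">
        <attribute name="Name" type="String">pyruvate</attribute>
        <attribute name="Marking" type="Integer">0</attribute>
      </node>
    </nodeclass>
    <nodeclass count="1" name="Transition">
      <node id="3" net="1">
        <attribute name="Name" type="String">glycolysis</attribute>
        <attribute name="Rate" type="Double">0.5</attribute>
      </node>
    </nodeclass>
    <nodeclass count="1" name="Comment">
      <node id="9" net="1">
        <attribute name="Comment" type="String">a drawing annotation</attribute>
      </node>
    </nodeclass>
  </nodeclasses>
  <edgeclasses count="1">
    <edgeclass count="2" name="Edge">
      <edge source="1" target="3" id="4">
        <attribute name="Multiplicity" type="Integer">1</attribute>
      </edge>
      <edge source="3" target="2" id="5">
        <attribute name="Multiplicity" type="Integer">2</attribute>
      </edge>
    </edgeclass>
  </edgeclasses>
</Snoopy>
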