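<?xml version='1.0' encoding='UTF-8'?>
<patientRecord version="1">
  <patient id="P1" birthDate="1955-03-10" baRef="digestive-ba-v1"/>
  <surgery id="e1" date="1988-06-14" title="Appendectomy">
    <step n="1">
      <narrative><![CDATA[Laparotomy, ligation of the appendix base, appendectomy.]]></narrative>
      <resect structure="appendix" scope="whole"/>
    </step>
  </surgery>
  <surgery id="e2" date="1992-09-03" title="Relaparotomy with adhesiolysis">
    <step n="1">
      <narrative><![CDATA[Extensive adhesiolysis; bowel intact, no resection.]]></narrative>
    </step>
  </surgery>
  <surgery id="e3" date="1995-02-20" title="Relaparotomy with adhesiolysis">
    <step n="1">
      <narrative><![CDATA[Recurrent adhesions divided sharply; no resection.]]></narrative>
    </step>
  </surgery>
  <surgery id="e4" date="2005-11-08" title="Left hemicolectomy">
    <step n="1">
      <narrative><![CDATA[Mobilization of the splenic flexure, resection of the distal transverse colon, the descending colon and the proximal sigmoid; transverse-sigmoid anastomosis.]]></narrative>
      <resect structure="transverse_colon" scope="interval" startMm="300" endMm="450"/>
      <resect structure="descending_colon" scope="whole"/>
      <resect structure="sigmoid_colon" scope="interval" startMm="0" endMm="100"/>
      <reconstruct id="al_p1_colo" from="transverse_colon" fromOffsetMm="300" to="sigmoid_colon" toOffsetMm="100" kind="colocolostomy" relation="luminal"/>
    </step>
  </surgery>
  <surgery id="e5" date="2014-05-27" title="Esophageal resection with gastric sleeve">
    <step n="1">
      <narrative><![CDATA[Subtotal esophagectomy for distal esophageal carcinoma.]]></narrative>
      <resect structure="esophagus" scope="interval" startMm="100" endMm="250"/>
    </step>
    <step n="2">
      <narrative><![CDATA[Formation of a gastric sleeve conduit; cervical gastroesophagostomy.]]></narrative>
      <biometric structure="stomach" attribute="diameter_mm" value="40"/>
      <reconstruct id="al_p1_ge" from="esophagus" fromOffsetMm="100" to="stomach" toOffsetMm="0" kind="gastroesophagostomy" relation="luminal"/>
    </step>
  </surgery>
</patientRecord>
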