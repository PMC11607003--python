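<?xml version='1.0' encoding='UTF-8'?>
<patientRecord version="1">
  <patient id="P2" birthDate="1960-07-01" baRef="digestive-ba-v1"/>
  <surgery id="e1" date="1985-04-11" title="Cholecystectomy">
    <step n="1">
      <narrative><![CDATA[Laparoscopic cholecystectomy; the cystic duct is clipped and divided, the gallbladder removed.]]></narrative>
      <resect structure="gallbladder" scope="whole"/>
      <resect structure="cystic_duct" scope="whole"/>
    </step>
  </surgery>
  <surgery id="e2" date="1998-08-23" title="Ileocecal resection">
    <step n="1">
      <narrative><![CDATA[Resection of the terminal ileum and cecum including the appendix; ileo-ascending anastomosis.]]></narrative>
      <resect structure="ileum" scope="interval" startMm="2800" endMm="3000"/>
      <resect structure="appendix" scope="whole"/>
      <resect structure="cecum" scope="whole"/>
      <reconstruct id="al_p2_ileocol" from="ileum" fromOffsetMm="2800" to="ascending_colon" toOffsetMm="0" kind="ileocolostomy" relation="luminal"/>
    </step>
  </surgery>
  <surgery id="e3" date="2005-03-30" title="Relaparotomy, ileum segment resection">
    <step n="1">
      <narrative><![CDATA[Segmental resection of a strictured mid-ileum loop; end-to-end ileoileostomy.]]></narrative>
      <resect structure="ileum" scope="interval" startMm="1500" endMm="1900"/>
      <reconstruct id="al_p2_ileo" from="ileum" fromOffsetMm="1500" to="ileum" toOffsetMm="1900" kind="ileoileostomy" relation="luminal"/>
    </step>
  </surgery>
  <surgery id="e4" date="2013-10-05" title="Left hemicolectomy">
    <step n="1">
      <narrative><![CDATA[Oncologic left hemicolectomy for colon carcinoma; transverse-sigmoid anastomosis.]]></narrative>
      <resect structure="transverse_colon" scope="interval" startMm="300" endMm="450"/>
      <resect structure="descending_colon" scope="whole"/>
      <resect structure="sigmoid_colon" scope="interval" startMm="0" endMm="100"/>
      <reconstruct id="al_p2_colo" from="transverse_colon" fromOffsetMm="300" to="sigmoid_colon" toOffsetMm="100" kind="colocolostomy" relation="luminal"/>
    </step>
  </surgery>
  <surgery id="e5" date="2020-06-18" title="Pancreatic head resection with partial SMV resection">
    <step n="1">
      <narrative><![CDATA[Duodenum-preserving resection of the pancreatic head for carcinoma with en-bloc partial resection of the infiltrated superior mesenteric vein.]]></narrative>
      <resect structure="pancreas" scope="interval" startMm="100" endMm="150"/>
      <resect structure="superior_mesenteric_vein" scope="interval" startMm="40" endMm="70"/>
    </step>
    <step n="2">
      <narrative><![CDATA[Venous end-to-end reconstruction; pancreaticojejunostomy of the remnant.]]></narrative>
      <reconstruct id="al_p2_smv" from="superior_mesenteric_vein" fromOffsetMm="40" to="superior_mesenteric_vein" toOffsetMm="70" kind="venous end-to-end anastomosis" relation="venous"/>
      <reconstruct id="al_p2_pj" from="pancreas" fromOffsetMm="100" to="jejunum" toOffsetMm="600" kind="pancreaticojejunostomy" relation="pancreatic"/>
    </step>
  </surgery>
</patientRecord>
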