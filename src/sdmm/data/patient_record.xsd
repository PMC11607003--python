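<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="relation">
    <xs:restriction base="xs:string">
      <xs:enumeration value="luminal"/>
      <xs:enumeration value="arterial"/>
      <xs:enumeration value="venous"/>
      <xs:enumeration value="portal"/>
      <xs:enumeration value="biliary"/>
      <xs:enumeration value="pancreatic"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="scope">
    <xs:restriction base="xs:string">
      <xs:enumeration value="whole"/>
      <xs:enumeration value="interval"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="biometricAttribute">
    <xs:restriction base="xs:string">
      <xs:enumeration value="length_mm"/>
      <xs:enumeration value="diameter_mm"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="patientRecord">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="patient">
          <xs:complexType>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="birthDate" type="xs:date" use="required"/>
            <xs:attribute name="baRef" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="surgery" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="step" minOccurs="1" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="narrative" type="xs:string" minOccurs="0"/>
                    <xs:choice minOccurs="0" maxOccurs="unbounded">
                      <xs:element name="resect">
                        <xs:complexType>
                          <xs:attribute name="structure" type="xs:string" use="required"/>
                          <xs:attribute name="scope" type="scope" use="required"/>
                          <xs:attribute name="startMm" type="xs:double"/>
                          <xs:attribute name="endMm" type="xs:double"/>
                        </xs:complexType>
                      </xs:element>
                      <xs:element name="reconstruct">
                        <xs:complexType>
                          <xs:attribute name="id" type="xs:string" use="required"/>
                          <xs:attribute name="from" type="xs:string" use="required"/>
                          <xs:attribute name="fromOffsetMm" type="xs:double" use="required"/>
                          <xs:attribute name="to" type="xs:string" use="required"/>
                          <xs:attribute name="toOffsetMm" type="xs:double" use="required"/>
                          <xs:attribute name="kind" type="xs:string" use="required"/>
                          <xs:attribute name="relation" type="relation" use="required"/>
                          <xs:attribute name="lengthMm" type="xs:double"/>
                        </xs:complexType>
                      </xs:element>
                      <xs:element name="biometric">
                        <xs:complexType>
                          <xs:attribute name="structure" type="xs:string" use="required"/>
                          <xs:attribute name="attribute" type="biometricAttribute" use="required"/>
                          <xs:attribute name="value" type="xs:double" use="required"/>
                        </xs:complexType>
                      </xs:element>
                    </xs:choice>
                  </xs:sequence>
                  <xs:attribute name="n" type="xs:positiveInteger" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="date" type="xs:date" use="required"/>
            <xs:attribute name="title" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required" fixed="1"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
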