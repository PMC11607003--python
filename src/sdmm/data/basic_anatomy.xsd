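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

  <xs:element name="basicAnatomy">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="organClass" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="name" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="structure" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="name" type="xs:string" use="required"/>
            <xs:attribute name="class" type="xs:string" use="required"/>
            <xs:attribute name="parent" type="xs:string"/>
            <xs:attribute name="attachmentOffsetMm" type="xs:double"/>
            <xs:attribute name="lengthMm" type="xs:double" use="required"/>
            <xs:attribute name="diameterMm" type="xs:double"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="naturalLink" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="from" type="xs:string" use="required"/>
            <xs:attribute name="fromOffsetMm" type="xs:double"/>
            <xs:attribute name="to" type="xs:string" use="required"/>
            <xs:attribute name="toOffsetMm" type="xs:double"/>
            <xs:attribute name="relation" type="relation" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="landmark" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="name" type="xs:string" use="required"/>
            <xs:attribute name="structure" type="xs:string" use="required"/>
            <xs:attribute name="offsetMm" type="xs:double" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required" fixed="1"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
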