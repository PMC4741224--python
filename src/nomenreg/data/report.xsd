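<?xml version="1.0" encoding="UTF-8"?>
<!-- Response-report dialect: one element per submitted act (and author)
     carrying exactly one of identifier / error message / pending marker. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="statusType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="registered"/>
      <xs:enumeration value="error"/>
      <xs:enumeration value="pending"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="outcomeType">
    <xs:sequence>
      <xs:element name="identifier" type="xs:string" minOccurs="0"/>
      <xs:element name="message" type="xs:string" minOccurs="0"/>
      <xs:element name="pending-ref" type="xs:string" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="index" type="xs:nonNegativeInteger" use="required"/>
    <xs:attribute name="status" type="statusType" use="required"/>
    <xs:attribute name="action">
      <xs:simpleType>
        <xs:restriction base="xs:string">
          <xs:enumeration value="inserted"/>
          <xs:enumeration value="updated"/>
        </xs:restriction>
      </xs:simpleType>
    </xs:attribute>
  </xs:complexType>

  <xs:element name="registration-report">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="acts">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="act" type="outcomeType" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="authors">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="author" type="outcomeType" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="article-id" type="xs:string"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
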